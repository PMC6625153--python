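"""Treatment response by genotype and survival endpoints.

Binary ELN-style response categories come from the published response
fixture; survival times are not published at subject level, so the
Kaplan-Meier / log-rank half of the example runs on a simulated cohort
whose GSTM1-null cases respond more slowly (hazard 0.02 vs 0.06 per
month), mirroring the published qualitative finding.
"""

from gstassoc import (
    SimulationConfig,
    SurvivalConfig,
    attach_survival,
    generate_cohort,
    generate_fixture,
    gstm1_null,
    km_estimate,
    logrank_test,
    mmr_events,
    response_table,
)

# Response categories at 3 and 6 months, by GSTM1.
cases = generate_fixture("table5_gstm1")
for endpoint, label in (("mcyr_3m", "MCyR at 3 months"),
                        ("ccyr_6m", "CCyR at 6 months")):
    result = response_table(cases, gstm1_null, endpoint, "GSTM1 null")
    counts = result.counts
    print(f"{label}: null {counts.a}/{counts.a + counts.b} vs "
          f"present {counts.c}/{counts.c + counts.d} responders, "
          f"p={result.test.p_value:.4f} [{result.test.method}]")
print("  -> GSTM1-null patients reach cytogenetic milestones less often.\n")

# Simulated time-to-MMR with genotype-dependent hazards.
records = generate_cohort(SimulationConfig(seed=11))
records = attach_survival(records, SurvivalConfig(), seed=12)
case_records = [r for r in records if r.group == "case"]
times, events, _ = mmr_events(case_records)
curve = km_estimate(times, events)
print(f"time-to-MMR (simulated, n={len(times)}): "
      f"{curve.n_events} responses, {curve.n_censored} censored")
print(f"  S(12 months) = {curve.survival_at(12):.3f} "
      "(fraction still without MMR at one year)")

labels = [r.gstm1 for r in case_records]
lr = logrank_test(labels, times, events)
print(f"log-rank GSTM1 null vs present: chi2={lr.statistic:.2f}, "
      f"p={lr.p_value:.4f}")
print(f"  observed events {lr.observed}, expected {lr.expected}")
print("  -> under these hazards the genotype gap is detectable at n=104.")
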