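"""Fixture reconstruction and the retrospective-tilt cohort simulator."""

import numpy as np
import pytest

from gstassoc import (
    FixtureSpec,
    SimulationConfig,
    SurvivalConfig,
    aggregate_2x2,
    attach_survival,
    field_equals,
    fixture_manifest,
    generate_cohort,
    generate_fixture,
    genotype_counts,
    gstm1_null,
    gstp1_variant,
    gstt1_null,
    joint_strata,
    km_estimate,
    logrank_test,
    odds_ratio,
    smoker,
    stratum_odds_ratios,
)
from gstassoc._tables import (
    DEMOGRAPHICS,
    GENE_GENE,
    GENE_SMOKING,
    GENOTYPES,
    RESPONSE,
)

PREDICATES = {
    "gstm1": gstm1_null,
    "gstt1": gstt1_null,
    "gstp1": gstp1_variant,
    "smoking": smoker,
}


# ---------------------------------------------------------------------------
# fixture mode


@pytest.mark.parametrize("pair", sorted(GENE_GENE) + sorted(GENE_SMOKING))
def test_pair_block_fixtures_round_trip(pair):
    records = generate_fixture(pair)
    field1, field2 = pair.split("_")
    table = joint_strata(records, PREDICATES[field1], PREDICATES[field2])
    published = (GENE_GENE | GENE_SMOKING)[pair]
    for group_index, group in enumerate(("case", "control")):
        for levels, count in published[group].items():
            assert table.stratum(*levels)[group_index] == count


@pytest.mark.parametrize("locus", sorted(GENOTYPES))
def test_genotype_block_fixtures_round_trip(locus):
    records = generate_fixture(locus)
    counts = genotype_counts(records, locus)
    for group in ("case", "control"):
        observed = dict(zip(counts.classes, counts.group_counts(group)))
        assert observed == GENOTYPES[locus][group]


def test_joint_fixture_reproduces_all_margin_tables(study_records):
    # every pairwise block simultaneously, from one record set
    for pair, published in (GENE_GENE | GENE_SMOKING).items():
        field1, field2 = pair.split("_")
        table = joint_strata(
            study_records, PREDICATES[field1], PREDICATES[field2]
        )
        for group_index, group in enumerate(("case", "control")):
            for levels, count in published[group].items():
                assert table.stratum(*levels)[group_index] == count, (pair, levels)
    # demographics
    smoking = aggregate_2x2(study_records, smoker)
    assert (smoking.a, smoking.c) == (57, 47)
    assert (smoking.b, smoking.d) == (31, 73)


def test_joint_fixture_carries_gstm1_response_block(study_records):
    cases = [r for r in study_records if r.group == "case"]
    for endpoint, per_group in RESPONSE["table5_gstm1"].items():
        if endpoint == "grouping":
            continue
        for genotype, (responders, non_responders) in per_group.items():
            token = {"mcyr_3m": "yes", "ccyr_6m": "yes",
                     "bcrabl_3m": "le10pct", "bcrabl_6m": "lt1pct"}[endpoint]
            subset = [r for r in cases if r.gstm1 == genotype]
            observed = sum(getattr(r, endpoint) == token for r in subset)
            assert observed == responders
            assert len(subset) == responders + non_responders


def test_fixture_age_summaries_exact(study_records):
    from gstassoc import cohort_summary

    summary = cohort_summary(study_records)
    for group in ("case", "control"):
        mean, sd = DEMOGRAPHICS["age_mean_sd"][group]
        assert summary.age_mean_sd[group][0] == pytest.approx(mean, abs=1e-9)
        assert summary.age_mean_sd[group][1] == pytest.approx(sd, abs=1e-9)


def test_fixture_manifest_notes_response_inconsistency():
    manifest = fixture_manifest("paper-all")
    assert "table5_gstp1" in manifest["excluded"]
    assert "table5_gstm1" in manifest["reproduces"]


def test_inconsistent_custom_spec_rejected():
    counts = {
        "case": {"present": 35, "null": 70},  # sums to 105 > 104
        "control": {"present": 53, "null": 51},
    }
    with pytest.raises(ValueError, match="105"):
        generate_fixture(FixtureSpec("gstm1", counts=counts))


def test_fixture_deterministic():
    first = generate_fixture("paper-all")
    second = generate_fixture("paper-all")
    assert [vars(r) for r in first] == [vars(r) for r in second]


# ---------------------------------------------------------------------------
# model mode


def test_null_model_profiles_balanced():
    config = SimulationConfig(
        n_cases=20000, n_controls=20000,
        effect_ors={}, seed=11,
    )
    records = generate_cohort(config)
    table = aggregate_2x2(records, gstm1_null)
    assert odds_ratio(table).or_estimate == pytest.approx(1.0, abs=0.1)
    table = aggregate_2x2(records, smoker)
    assert odds_ratio(table).or_estimate == pytest.approx(1.0, abs=0.1)


def test_simulation_deterministic_under_seed():
    config = SimulationConfig(n_cases=200, n_controls=200, seed=5)
    first = generate_cohort(config)
    second = generate_cohort(config)
    assert [vars(r) for r in first] == [vars(r) for r in second]


def test_simulation_gstp1_controls_near_hwe():
    config = SimulationConfig(n_cases=10, n_controls=30000, seed=2)
    records = generate_cohort(config)
    counts = genotype_counts(records, "gstp1")
    n_aa, n_ag, n_gg = counts.group_counts("control")
    total = n_aa + n_ag + n_gg
    q = 43 / 208
    assert n_gg / total == pytest.approx(q * q, abs=0.01)
    assert n_ag / total == pytest.approx(2 * q * (1 - q), abs=0.01)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="probability"):
        SimulationConfig(control_smoking_prev=1.5)
    with pytest.raises(ValueError, match="positive"):
        SimulationConfig(effect_ors={"smoking": -1.0})
    with pytest.raises(ValueError, match="unknown effect term"):
        SimulationConfig(effect_ors={"coffee": 2.0})


# ---------------------------------------------------------------------------
# attach_survival


def test_zero_hazard_means_all_censored():
    records = generate_cohort(SimulationConfig(n_cases=50, n_controls=5, seed=3))
    config = SurvivalConfig(
        response_hazard_by_gstm1={"null": 0.0, "present": 0.0},
        efs_hazard_by_gstm1={"null": 0.0, "present": 0.0},
    )
    out = attach_survival(records, config, seed=4)
    cases = [r for r in out if r.group == "case"]
    assert all(r.mmr_event == "no" and r.efs_event == "no" for r in cases)
    assert all(r.mcyr_3m == "no" for r in cases)


def test_attach_survival_deterministic_and_case_only():
    records = generate_cohort(SimulationConfig(n_cases=30, n_controls=30, seed=9))
    config = SurvivalConfig()
    first = attach_survival(records, config, seed=1)
    second = attach_survival(records, config, seed=1)
    assert [vars(r) for r in first] == [vars(r) for r in second]
    controls = [r for r in first if r.group == "control"]
    assert all(r.mmr_time is None for r in controls)


def test_equal_hazards_logrank_type_i_error():
    # GSTM1-null vs present with identical response hazards: the
    # log-rank rejection rate at alpha=0.05 stays near nominal.
    rng = np.random.default_rng(1)
    rejections = 0
    n_reps = 1000
    for _ in range(n_reps):
        n = 200
        genotypes = np.where(rng.random(n) < 0.5, "null", "present")
        event_times = rng.exponential(1 / 0.03, n)
        censor_times = rng.uniform(0, 72, n)
        observed = np.minimum(event_times, censor_times)
        events = event_times <= censor_times
        result = logrank_test(genotypes, observed, events)
        rejections += result.p_value < 0.05
    assert 0.03 <= rejections / n_reps <= 0.07


def test_hazard_ratio_orders_km_medians():
    # hazard ratio 3 between strata: KM medians come out ordered in
    # nearly all replicates.
    def km_median(times, events):
        curve = km_estimate(times, events)
        for t, s in zip(curve.times, curve.survival):
            if s <= 0.5:
                return t
        return np.inf

    rng = np.random.default_rng(77)
    ordered = 0
    n_reps = 200
    for _ in range(n_reps):
        fast = rng.exponential(1 / 0.09, 100)
        slow = rng.exponential(1 / 0.03, 100)
        censor = rng.uniform(0, 72, 200)
        times = np.concatenate([fast, slow])
        events = times <= censor
        observed = np.minimum(times, censor)
        median_fast = km_median(observed[:100], events[:100])
        median_slow = km_median(observed[100:], events[100:])
        ordered += median_fast < median_slow
    assert ordered / n_reps >= 0.95
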