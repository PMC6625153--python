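"""Replication pipeline and report rendering.

:func:`run_pipeline` executes the full analysis sequence on a cohort —
demographics, single-locus association under the genetic models,
Hardy-Weinberg checks, gene-gene and gene-smoking additive interaction,
treatment-response tables and (when survival fields are present)
Kaplan-Meier / log-rank endpoints — and returns a plain nested dict.
:func:`render_report` serialises it as a stable human-readable text
table (fixed rounding: ORs/RERI/SI to 2 decimals, AP to 3, p to 3 or
"<0.001") or as JSON with full precision.  :func:`replicate` runs the
pipeline on the built-in fixture and places the published values side
by side with match flags.
"""

from __future__ import annotations

import json
import math
from typing import Optional

from . import _tables
from .association import (
    GeneticModelSpec,
    allele_table,
    association_test,
    genetic_model_table,
    hwe_test,
    odds_ratio,
    pearson_chi2,
    per_allele_logistic,
    t_test_from_summary,
)
from .cohort import (
    SubjectRecord,
    aggregate_2x2,
    cohort_summary,
    field_equals,
    genotype_counts,
    gstm1_null,
    gstp1_variant,
    gstt1_null,
    smoker,
)
from .interaction import interaction_analysis
from .outcomes import (
    ENDPOINT_RESPONDER,
    km_estimate,
    logrank_test,
    mmr_events,
    response_table,
)
from .synthetic import generate_fixture

__all__ = ["run_pipeline", "render_report", "replicate"]


def _or_block(result) -> dict:
    return {
        "or": result.or_estimate,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "log_or": result.log_or,
        "se_log_or": result.se_log_or,
        "estimable": result.estimable,
        "zero_cell": result.zero_cell,
    }


def _test_block(result) -> dict:
    return {
        "statistic": result.statistic,
        "df": result.df,
        "p": result.p_value,
        "method": result.method,
    }


def _demographics_block(records) -> dict:
    summary = cohort_summary(records)
    block: dict = {
        "n": summary.n,
        "sex": summary.sex,
        "smoking": summary.smoking,
        "age_mean_sd": summary.age_mean_sd,
    }
    sex = summary.sex
    if min(v for g in sex.values() for v in g.values()) > 0:
        block["sex_test"] = _test_block(pearson_chi2(
            [[sex["case"]["male"], sex["case"]["female"]],
             [sex["control"]["male"], sex["control"]["female"]]]
        ))
    smoking = summary.smoking
    if min(v for g in smoking.values() for v in g.values()) > 0:
        block["smoking_test"] = _test_block(pearson_chi2(
            [[smoking["case"]["smoker"], smoking["case"]["nonsmoker"]],
             [smoking["control"]["smoker"], smoking["control"]["nonsmoker"]]]
        ))
    (m1, s1), (m2, s2) = summary.age_mean_sd["case"], summary.age_mean_sd["control"]
    if all(map(math.isfinite, (m1, s1, m2, s2))) and s1 > 0 and s2 > 0:
        block["age_t_p"] = t_test_from_summary(
            m1, s1, summary.n["case"] - summary.age_n_missing["case"],
            m2, s2, summary.n["control"] - summary.age_n_missing["control"],
        )
    return block


def _single_locus_block(records, alpha: float) -> dict:
    block: dict = {}
    for locus in ("gstm1", "gstt1"):
        counts = genotype_counts(records, locus)
        # Deletion assays see only present vs null; the "recessive"
        # contrast is present (functional) as exposure vs null.
        table = aggregate_2x2(
            records, field_equals(locus, "present"),
            exposure_label=f"{locus} present",
        )
        block[locus] = {
            "counts": {g: dict(zip(counts.classes, counts.group_counts(g)))
                       for g in ("case", "control")},
            "recessive": {
                "or": _or_block(odds_ratio(table, alpha=alpha)),
                "test": _test_block(association_test(table)),
            },
        }
    counts = genotype_counts(records, "gstp1")
    gstp1: dict = {
        "counts": {g: dict(zip(counts.classes, counts.group_counts(g)))
                   for g in ("case", "control")},
        "hwe": {},
    }
    for group in ("case", "control"):
        observed = counts.group_counts(group)
        if sum(observed) > 0:
            result = hwe_test(observed)
            gstp1["hwe"][group] = {
                "allele_freq": result.allele_freq,
                "chi2": result.chi2,
                "p": result.p_value,
                "degenerate": result.degenerate,
            }
    for model in ("recessive", "dominant"):
        spec = GeneticModelSpec(model=model)
        table = genetic_model_table(counts, spec)
        or_result = odds_ratio(table, alpha=alpha)
        entry = {
            "or": _or_block(or_result),
            "test": _test_block(association_test(table)),
        }
        if or_result.estimable:
            # Wald p on the log OR, reported beside the contingency p.
            from scipy import stats as _stats
            z = or_result.log_or / or_result.se_log_or
            entry["wald_p"] = float(2 * _stats.norm.sf(abs(z)))
        gstp1[model] = entry
    gstp1["additive"] = _or_block(per_allele_logistic(counts, alpha=alpha))
    alleles = allele_table(counts)
    gstp1["allele"] = {
        "or": _or_block(odds_ratio(alleles, alpha=alpha)),
        "test": _test_block(association_test(alleles)),
    }
    block["gstp1"] = gstp1
    return block


_PAIRS = {
    "gstm1_gstt1": (gstm1_null, gstt1_null, "GSTM1 null", "GSTT1 null"),
    "gstm1_gstp1": (gstm1_null, gstp1_variant, "GSTM1 null", "GSTP1 AG/GG"),
    "gstt1_gstp1": (gstt1_null, gstp1_variant, "GSTT1 null", "GSTP1 AG/GG"),
    "gstm1_smoking": (gstm1_null, smoker, "GSTM1 null", "smoker"),
    "gstt1_smoking": (gstt1_null, smoker, "GSTT1 null", "smoker"),
    "gstp1_smoking": (gstp1_variant, smoker, "GSTP1 AG/GG", "smoker"),
}


def _interaction_block(records, pair: str, alpha: float) -> dict:
    factor1, factor2, label1, label2 = _PAIRS[pair]
    table, interaction = interaction_analysis(
        records, factor1, factor2, label1, label2, alpha=alpha
    )
    strata = {}
    for name, (l1, l2) in zip(
        ("or11", "or10", "or01"), ((1, 1), (1, 0), (0, 1))
    ):
        cases, controls = table.stratum(l1, l2)
        ref_cases, ref_controls = table.stratum(0, 0)
        entry = {
            "cases": cases,
            "controls": controls,
            **_or_block(getattr(interaction, name)),
        }
        if cases + controls > 0 and ref_cases + ref_controls > 0:
            from .cohort import TwoByTwoTable
            entry["test"] = _test_block(association_test(
                TwoByTwoTable(cases, controls, ref_cases, ref_controls)
            ))
        strata[name] = entry
    ref_cases, ref_controls = table.stratum(0, 0)
    return {
        "factor1": label1,
        "factor2": label2,
        "strata": strata,
        "reference": {"cases": ref_cases, "controls": ref_controls},
        "n_excluded": table.n_excluded,
        "reri": interaction.reri,
        "ap": interaction.ap,
        "si": interaction.si,
        "convention_applied": interaction.convention_applied,
    }


def _response_block(records, alpha: float) -> dict:
    cases = [r for r in records if r.group == "case"]
    block: dict = {}
    groupings = {
        "gstm1_null_vs_present": (gstm1_null, "GSTM1 null vs present"),
        "gstp1_aa_vs_variant": (
            field_equals("gstp1", "AA"), "GSTP1 AA vs AG/GG",
        ),
    }
    for key, (predicate, label) in groupings.items():
        entry = {}
        for endpoint in ENDPOINT_RESPONDER:
            if all(getattr(r, endpoint) is None for r in cases):
                continue
            result = response_table(cases, predicate, endpoint, label)
            entry[endpoint] = {
                "counts": {
                    "group1": (result.counts.a, result.counts.b),
                    "group2": (result.counts.c, result.counts.d),
                },
                "test": _test_block(result.test),
                "n_missing": result.n_missing,
            }
        if entry:
            block[key] = entry
    return block


def _survival_block(records) -> dict:
    cases = [r for r in records if r.group == "case"]
    block: dict = {}
    for endpoint, extractor in (("mmr", mmr_events), ("efs", None)):
        from .outcomes import efs_events
        extractor = extractor or efs_events
        times, events, missing = extractor(cases)
        if times.size == 0:
            continue
        curve = km_estimate(times, events)
        entry = {
            "n": int(times.size),
            "n_events": curve.n_events,
            "n_censored": curve.n_censored,
            "n_missing": missing,
        }
        labels, label_times, label_events = [], [], []
        for record in cases:
            time = getattr(record, f"{endpoint}_time")
            event = getattr(record, f"{endpoint}_event")
            if time is None or event is None or record.gstm1 is None:
                continue
            labels.append(record.gstm1)
            label_times.append(time)
            label_events.append(event == "yes")
        if len(set(labels)) == 2:
            result = logrank_test(labels, label_times, label_events)
            entry["logrank_by_gstm1"] = {
                "statistic": result.statistic,
                "p": result.p_value,
                "observed": result.observed,
                "expected": result.expected,
            }
        block[endpoint] = entry
    return block


def run_pipeline(
    records: list[SubjectRecord], alpha: float = 0.05
) -> dict:
    """Full analysis report for a cohort, as a nested plain dict."""
    report: dict = {
        "alpha": alpha,
        "demographics": _demographics_block(records),
        "single_locus": _single_locus_block(records, alpha),
        "gene_gene": {
            pair: _interaction_block(records, pair, alpha)
            for pair in ("gstm1_gstt1", "gstm1_gstp1", "gstt1_gstp1")
        },
        "gene_smoking": {
            pair: _interaction_block(records, pair, alpha)
            for pair in ("gstm1_smoking", "gstt1_smoking", "gstp1_smoking")
        },
    }
    response = _response_block(records, alpha)
    if response:
        report["response"] = response
    survival = _survival_block(records)
    if survival:
        report["survival"] = survival
    return report


def replicate(alpha: float = 0.05) -> dict:
    """Pipeline on the built-in fixture with published values attached.

    Each comparable quantity carries ``computed``, ``published`` and a
    ``match`` flag: True when the computed value agrees with the
    published one within one unit in the published value's last printed
    digit (the published tables mix rounding and truncation).
    """
    records = generate_fixture("paper-all")
    report = run_pipeline(records, alpha=alpha)

    def compare(computed: Optional[float], published: Optional[float]) -> dict:
        if published is None or computed is None or not math.isfinite(computed):
            return {
                "computed": computed, "published": published, "match": None,
            }
        text = f"{published}"
        decimals = len(text.split(".")[1]) if "." in text else 0
        ulp = 10.0 ** (-decimals)
        return {
            "computed": computed,
            "published": published,
            "match": bool(abs(computed - published) <= ulp + 1e-12),
        }

    printed = _tables.PRINTED
    single = report["single_locus"]
    comparison = {
        "gstm1_recessive_or": compare(
            single["gstm1"]["recessive"]["or"]["or"], printed["gstm1_recessive_or"]
        ),
        "gstt1_recessive_or": compare(
            single["gstt1"]["recessive"]["or"]["or"], printed["gstt1_recessive_or"]
        ),
        "gstp1_recessive_or": compare(
            single["gstp1"]["recessive"]["or"]["or"], printed["gstp1_recessive_or"]
        ),
        "gstp1_dominant_or": compare(
            single["gstp1"]["dominant"]["or"]["or"], printed["gstp1_dominant_or"]
        ),
        "gstp1_additive_or": compare(
            single["gstp1"]["additive"]["or"], printed["gstp1_additive_or"]
        ),
        "gstp1_allele_or": compare(
            single["gstp1"]["allele"]["or"]["or"], printed["gstp1_allele_or"]
        ),
        "hwe_case_p": compare(
            single["gstp1"]["hwe"]["case"]["p"], printed["hwe_p"]["case"]
        ),
        "hwe_control_p": compare(
            single["gstp1"]["hwe"]["control"]["p"], printed["hwe_p"]["control"]
        ),
        "age_t_p": compare(
            report["demographics"]["age_t_p"], printed["age_t_p"]
        ),
    }
    for section, printed_section in (
        ("gene_gene", printed["gene_gene"]),
        ("gene_smoking", printed["gene_smoking"]),
    ):
        for pair, values in printed_section.items():
            block = report[section][pair]
            for key, published in values.items():
                if key in ("or11", "or10", "or01"):
                    computed = block["strata"][key]["or"]
                    if not block["strata"][key]["estimable"]:
                        computed = None
                elif key in ("reri", "ap", "si"):
                    computed = block[key]
                comparison[f"{pair}_{key}"] = compare(computed, published)
    report["replication"] = comparison
    return report


# ---------------------------------------------------------------------------
# Rendering


def _fmt_p(p: Optional[float]) -> str:
    if p is None or not math.isfinite(p):
        return "-"
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def _fmt_or(value: Optional[float], decimals: int = 2) -> str:
    if value is None or not math.isfinite(value):
        return "-"
    return f"{value:.{decimals}f}"


def _render_text(report: dict) -> str:
    lines: list[str] = []
    demographics = report["demographics"]
    lines.append("== Cohort ==")
    lines.append(
        f"cases n={demographics['n']['case']}  "
        f"controls n={demographics['n']['control']}"
    )
    if "age_t_p" in demographics:
        lines.append(f"age t-test p={_fmt_p(demographics['age_t_p'])}")
    if "smoking_test" in demographics:
        lines.append(
            f"smoking chi2 p={_fmt_p(demographics['smoking_test']['p'])}"
        )
    lines.append("")
    lines.append("== Single-locus association ==")
    single = report["single_locus"]
    for locus in ("gstm1", "gstt1"):
        entry = single[locus]["recessive"]
        lines.append(
            f"{locus.upper()} recessive: OR={_fmt_or(entry['or']['or'])} "
            f"({_fmt_or(entry['or']['ci_low'])}-{_fmt_or(entry['or']['ci_high'])}) "
            f"p={_fmt_p(entry['test']['p'])} [{entry['test']['method']}]"
        )
    gstp1 = single["gstp1"]
    for model in ("recessive", "dominant"):
        entry = gstp1[model]
        lines.append(
            f"GSTP1 {model}: OR={_fmt_or(entry['or']['or'])} "
            f"({_fmt_or(entry['or']['ci_low'])}-{_fmt_or(entry['or']['ci_high'])}) "
            f"p={_fmt_p(entry['test']['p'])} [{entry['test']['method']}]"
        )
    additive = gstp1["additive"]
    lines.append(
        f"GSTP1 additive (per G allele): OR={_fmt_or(additive['or'], 3)} "
        f"({_fmt_or(additive['ci_low'], 3)}-{_fmt_or(additive['ci_high'], 3)})"
    )
    for group, entry in sorted(gstp1["hwe"].items()):
        lines.append(f"GSTP1 HWE {group}: p={_fmt_p(entry['p'])}")
    for section, title in (
        ("gene_gene", "Gene-gene interaction"),
        ("gene_smoking", "Gene-smoking interaction"),
    ):
        lines.append("")
        lines.append(f"== {title} ==")
        for pair, block in report[section].items():
            lines.append(f"-- {block['factor1']} x {block['factor2']} --")
            for name in ("or11", "or10", "or01"):
                stratum = block["strata"][name]
                flag = " [inestimable]" if not stratum["estimable"] else ""
                lines.append(
                    f"  {name.upper()}: {stratum['cases']}/{stratum['controls']} "
                    f"OR={_fmt_or(stratum['or'])}"
                    f" ({_fmt_or(stratum['ci_low'])}-{_fmt_or(stratum['ci_high'])})"
                    f"{flag}"
                )
            reference = block["reference"]
            lines.append(
                f"  REF : {reference['cases']}/{reference['controls']} OR=1"
            )
            convention = (
                " [zero-convention]"
                if any(block["convention_applied"].values()) else ""
            )
            lines.append(
                f"  RERI={_fmt_or(block['reri'])} AP={_fmt_or(block['ap'], 3)} "
                f"SI={_fmt_or(block['si'])}{convention}"
            )
    if "response" in report:
        lines.append("")
        lines.append("== Treatment response (cases) ==")
        for key, entries in report["response"].items():
            for endpoint, entry in entries.items():
                group1, group2 = entry["counts"]["group1"], entry["counts"]["group2"]
                lines.append(
                    f"{key} {endpoint}: {group1[0]}/{group1[0] + group1[1]} vs "
                    f"{group2[0]}/{group2[0] + group2[1]} "
                    f"p={_fmt_p(entry['test']['p'])} [{entry['test']['method']}]"
                )
    if "survival" in report:
        lines.append("")
        lines.append("== Survival endpoints (cases) ==")
        for endpoint, entry in report["survival"].items():
            line = (
                f"{endpoint.upper()}: n={entry['n']} events={entry['n_events']} "
                f"censored={entry['n_censored']}"
            )
            if "logrank_by_gstm1" in entry:
                line += (
                    f" log-rank(GSTM1) p="
                    f"{_fmt_p(entry['logrank_by_gstm1']['p'])}"
                )
            lines.append(line)
    if "replication" in report:
        lines.append("")
        lines.append("== Replication vs published values ==")
        for key, entry in sorted(report["replication"].items()):
            status = {True: "MATCH", False: "MISMATCH", None: "-"}[entry["match"]]
            computed = (
                "-" if entry["computed"] is None
                else f"{entry['computed']:.4f}"
            )
            lines.append(
                f"{key}: computed={computed} published={entry['published']} "
                f"{status}"
            )
    return "\n".join(lines) + "\n"


def render_report(report: dict, format: str = "text") -> str:
    """Serialise a report deterministically.

    ``text`` applies the fixed display rounding; ``structured`` emits
    sorted-key JSON with full precision (non-finite floats as strings).
    """
    if format == "structured":
        def default(obj):
            return str(obj)

        def clean(value):
            if isinstance(value, float) and not math.isfinite(value):
                return repr(value)
            if isinstance(value, dict):
                return {str(k): clean(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [clean(v) for v in value]
            return value

        return json.dumps(clean(report), sort_keys=True, indent=2,
                          default=default) + "\n"
    if format == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {format!r}")
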