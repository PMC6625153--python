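"""Two-factor joint stratification and additive-scale interaction.

Subjects are cross-classified by two binary risk factors (two genotypes,
or a genotype and smoking) into four exposure strata; each stratum's
odds of disease is compared with the doubly-unexposed reference stratum
(OR00 = 1 by construction).  On the additive scale the departure from
additivity of the two factors is summarised by

* RERI = OR11 - OR10 - OR01 + 1   (relative excess risk due to interaction),
* AP   = RERI / OR11              (attributable proportion due to interaction),
* SI   = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (synergy index).

Sparse strata: a stratum odds ratio with a zero cell is inestimable
(raw cross-product 0 or +inf).  Such a stratum contributes the value 0
to the three formulas, and the result flags the substitution.  This is
a statistically aggressive convention — a single empty cell can swing
RERI by whole units — so every application of it is flagged and logged.
Confidence intervals for the interaction measures come from a stratified
percentile bootstrap (the substitution rule makes delta-method standard
errors invalid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .association import OddsRatioResult, odds_ratio
from .cohort import Predicate, SubjectRecord, TwoByTwoTable

logger = logging.getLogger("gstassoc")

__all__ = [
    "JointStratificationTable",
    "InteractionResult",
    "BootstrapInterval",
    "joint_strata",
    "stratum_odds_ratios",
    "additive_interaction",
    "interaction_analysis",
    "interaction_ci_bootstrap",
]

#: Fixed stratum reporting order: (factor1, factor2) exposure levels.
STRATUM_ORDER = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass(frozen=True)
class JointStratificationTable:
    """Eight counts: (factor1 level, factor2 level, group) -> n, with
    level 1 = exposed and (0, 0) the reference stratum."""

    factor1_label: str
    factor2_label: str
    cells: dict  # (int, int, str) -> int
    n_excluded: int = 0

    def stratum(self, level1: int, level2: int) -> tuple:
        """(cases, controls) in one stratum."""
        return (
            self.cells[(level1, level2, "case")],
            self.cells[(level1, level2, "control")],
        )

    @property
    def total(self) -> int:
        return sum(self.cells.values())


@dataclass(frozen=True)
class InteractionResult:
    """Stratum odds ratios against the doubly-unexposed reference plus
    the additive-scale interaction measures.

    ``convention_applied`` maps stratum name -> bool, recording where an
    inestimable OR was replaced by 0 inside the formulas.  ``ap`` is
    None when OR11 is inestimable; ``si`` is None when its denominator
    is zero.
    """

    or11: OddsRatioResult
    or10: OddsRatioResult
    or01: OddsRatioResult
    reri: float
    ap: Optional[float]
    si: Optional[float]
    convention_applied: dict


@dataclass(frozen=True)
class BootstrapInterval:
    """Percentile bootstrap CIs for RERI/AP/SI.  ``n_undefined`` counts
    resamples where AP or SI was undefined; ``n_degenerate`` counts
    resamples with at least one empty-cell stratum (substitution rule
    applied)."""

    reri: tuple
    ap: tuple
    si: tuple
    point: "InteractionResult"
    n_boot: int
    n_degenerate: int
    n_undefined_ap: int
    n_undefined_si: int
    seed: int
    alpha: float


def joint_strata(
    records: Iterable[SubjectRecord],
    factor1: Predicate,
    factor2: Predicate,
    factor1_label: str = "factor1",
    factor2_label: str = "factor2",
) -> JointStratificationTable:
    """Cross-classify records by two binary factors and case status,
    excluding (and counting) records missing either factor."""
    cells = {(l1, l2, g): 0 for l1 in (0, 1) for l2 in (0, 1)
             for g in ("case", "control")}
    excluded = 0
    for record in records:
        v1, v2 = factor1(record), factor2(record)
        if v1 is None or v2 is None:
            excluded += 1
            continue
        cells[(int(v1), int(v2), record.group)] += 1
    return JointStratificationTable(
        factor1_label, factor2_label, cells, n_excluded=excluded
    )


def stratum_odds_ratios(
    table: JointStratificationTable, alpha: float = 0.05
) -> tuple[OddsRatioResult, OddsRatioResult, OddsRatioResult]:
    """(OR11, OR10, OR01): each exposure stratum's cases/controls versus
    the reference stratum, as cross-product odds ratios with Woolf CIs;
    zero-cell strata come back flagged inestimable."""
    ref_cases, ref_controls = table.stratum(0, 0)
    results = []
    for level1, level2 in STRATUM_ORDER[:3]:
        cases, controls = table.stratum(level1, level2)
        two_by_two = TwoByTwoTable(
            cases, controls, ref_cases, ref_controls,
            exposure_label=f"({table.factor1_label}={level1}, "
                           f"{table.factor2_label}={level2})",
        )
        results.append(odds_ratio(two_by_two, alpha=alpha))
    return tuple(results)


def _convention_value(result: OddsRatioResult) -> tuple[float, bool]:
    if result.estimable:
        return result.or_estimate, False
    return 0.0, True


def additive_interaction(
    or11: OddsRatioResult, or10: OddsRatioResult, or01: OddsRatioResult
) -> InteractionResult:
    """RERI, AP and SI from three stratum odds ratios (OR00 = 1).

    Unrounded estimates enter the formulas.  Any inestimable stratum OR
    contributes 0, with the substitution flagged per stratum and logged
    at warning level.
    """
    v11, f11 = _convention_value(or11)
    v10, f10 = _convention_value(or10)
    v01, f01 = _convention_value(or01)
    flags = {"or11": f11, "or10": f10, "or01": f01}
    if any(flags.values()):
        logger.warning(
            "additive_interaction: inestimable stratum OR(s) %s set to 0 "
            "in RERI/AP/SI",
            ", ".join(k for k, v in flags.items() if v),
        )
    reri = v11 - v10 - v01 + 1
    ap = None if (f11 or v11 == 0) else reri / v11
    denominator = (v10 - 1) + (v01 - 1)
    si = None if denominator == 0 else (v11 - 1) / denominator
    return InteractionResult(
        or11=or11, or10=or10, or01=or01, reri=reri, ap=ap, si=si,
        convention_applied=flags,
    )


def interaction_analysis(
    records: Iterable[SubjectRecord],
    factor1: Predicate,
    factor2: Predicate,
    factor1_label: str = "factor1",
    factor2_label: str = "factor2",
    alpha: float = 0.05,
) -> tuple[JointStratificationTable, InteractionResult]:
    """Convenience pipeline: stratify, estimate the three stratum ORs,
    and compute the additive-interaction measures."""
    table = joint_strata(records, factor1, factor2, factor1_label, factor2_label)
    or11, or10, or01 = stratum_odds_ratios(table, alpha=alpha)
    return table, additive_interaction(or11, or10, or01)


def _measures_from_cells(strata: np.ndarray, ref: np.ndarray):
    """Vector versions of the three measures from integer cell counts.

    ``strata``: shape (3, 2) rows OR11/OR10/OR01 as (cases, controls);
    ``ref``: (cases, controls).  Applies the zero-substitution rule.
    Returns (reri, ap, si, degenerate_flag) with nan for undefined.
    """
    values = np.zeros(3)
    degenerate = False
    for i, (cases, controls) in enumerate(strata):
        if 0 in (cases, controls, ref[0], ref[1]):
            values[i] = 0.0
            degenerate = True
        else:
            values[i] = (cases * ref[1]) / (controls * ref[0])
    v11, v10, v01 = values
    reri = v11 - v10 - v01 + 1
    ap = reri / v11 if v11 > 0 else np.nan
    denominator = (v10 - 1) + (v01 - 1)
    si = (v11 - 1) / denominator if denominator != 0 else np.nan
    return reri, ap, si, degenerate


def interaction_ci_bootstrap(
    records: Iterable[SubjectRecord],
    factor1: Predicate,
    factor2: Predicate,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    factor1_label: str = "factor1",
    factor2_label: str = "factor2",
) -> BootstrapInterval:
    """Percentile bootstrap CIs for RERI/AP/SI.

    Subjects are resampled with replacement *within* the case and
    control groups separately (the case-control design fixes the two
    group sizes).  Resamples with an empty-cell stratum go through the
    same zero-substitution rule as the point estimate and are counted.
    Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    records = list(records)
    table, point = interaction_analysis(
        records, factor1, factor2, factor1_label, factor2_label, alpha=alpha
    )
    # Precompute each complete-case record's stratum code (0..3).
    codes = {"case": [], "control": []}
    for record in records:
        v1, v2 = factor1(record), factor2(record)
        if v1 is None or v2 is None:
            continue
        codes[record.group].append(2 * int(v1) + int(v2))
    case_codes = np.asarray(codes["case"], dtype=np.int64)
    control_codes = np.asarray(codes["control"], dtype=np.int64)
    if case_codes.size == 0 or control_codes.size == 0:
        raise ValueError("bootstrap needs at least one case and one control")

    rng = np.random.default_rng(seed)
    reri = np.empty(n_boot)
    ap = np.empty(n_boot)
    si = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        case_sample = case_codes[
            rng.integers(0, case_codes.size, case_codes.size)
        ]
        control_sample = control_codes[
            rng.integers(0, control_codes.size, control_codes.size)
        ]
        case_counts = np.bincount(case_sample, minlength=4)
        control_counts = np.bincount(control_sample, minlength=4)
        # code 3 = (1,1), 2 = (1,0), 1 = (0,1), 0 = (0,0)
        strata = np.array(
            [
                (case_counts[3], control_counts[3]),
                (case_counts[2], control_counts[2]),
                (case_counts[1], control_counts[1]),
            ]
        )
        ref = np.array((case_counts[0], control_counts[0]))
        reri[b], ap[b], si[b], degenerate = _measures_from_cells(strata, ref)
        n_degenerate += degenerate

    def percentile_ci(values: np.ndarray) -> tuple:
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(finite, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return (float(lo), float(hi))

    if n_degenerate:
        logger.warning(
            "interaction_ci_bootstrap: zero-substitution applied in %d of %d "
            "resamples", n_degenerate, n_boot,
        )
    return BootstrapInterval(
        reri=percentile_ci(reri),
        ap=percentile_ci(ap),
        si=percentile_ci(si),
        point=point,
        n_boot=n_boot,
        n_degenerate=int(n_degenerate),
        n_undefined_ap=int(np.isnan(ap).sum()),
        n_undefined_si=int(np.isnan(si).sum()),
        seed=seed,
        alpha=alpha,
    )
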