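"""Case-control association statistics.

Odds ratios with Woolf (log-scale normal) confidence intervals, Pearson
and Fisher contingency tests with the small-cell decision rule, a
summary-statistic Welch t-test, the chi-square goodness-of-fit test for
Hardy-Weinberg equilibrium, recessive/dominant genetic-model collapses,
allele tables, and the per-allele (additive, dosage 0/1/2) logistic
regression fitted by maximum likelihood on grouped counts.

Conventions fixed here and used throughout the package:

* No continuity correction in the Pearson chi-square.
* Fisher's exact test is two-sided by the probability-mass rule and is
  chosen automatically when a cell is zero or an expected count is < 5.
* An odds ratio with any zero cell is *inestimable*: the raw
  cross-product (0, +inf or nan) is recorded, no CI is attached, and
  downstream interaction formulas apply an explicit substitution rule.
* No multiple-testing adjustment; raw two-sided p-values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import GenotypeCountTable, TwoByTwoTable

__all__ = [
    "OddsRatioResult",
    "ChiSquareResult",
    "HWEResult",
    "GeneticModelSpec",
    "odds_ratio",
    "pearson_chi2",
    "fisher_exact",
    "association_test",
    "t_test_from_summary",
    "hwe_test",
    "genetic_model_table",
    "allele_table",
    "per_allele_logistic",
]


@dataclass(frozen=True)
class OddsRatioResult:
    """Point estimate and Woolf CI for a 2x2 odds ratio.

    When any source cell is zero the estimate is flagged inestimable:
    ``or_estimate`` then carries the raw cross-product value (0.0, inf
    or nan) and the CI bounds are nan.
    """

    or_estimate: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    alpha: float
    estimable: bool
    zero_cell: bool


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: Optional[float]
    df: int
    p_value: float
    method: str  # pearson | fisher | hwe_gof | logrank


@dataclass(frozen=True)
class HWEResult:
    allele_freq: float
    expected_counts: tuple
    chi2: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class GeneticModelSpec:
    """How to collapse a three-genotype locus into a 2x2 exposure.

    ``recessive`` contrasts hom-variant vs the rest, ``dominant``
    contrasts variant carriers (het + hom-variant) vs hom-wild; the
    additive model is a dosage regression and is handled by
    :func:`per_allele_logistic` instead.  ``exposure_orientation``
    decides which side of the dichotomy is counted as exposed.
    """

    model: str  # recessive | dominant | additive
    risk_allele: str = "G"
    exposure_orientation: str = "wildtype_as_exposure"

    def __post_init__(self) -> None:
        if self.model not in ("recessive", "dominant", "additive"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        if self.exposure_orientation not in (
            "wildtype_as_exposure", "variant_as_exposure",
        ):
            raise ValueError(
                f"unknown orientation {self.exposure_orientation!r}"
            )


def odds_ratio(table: TwoByTwoTable, alpha: float = 0.05) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with Woolf CI
    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))."""
    a, b, c, d = table.a, table.b, table.c, table.d
    zero_cell = 0 in (a, b, c, d)
    if zero_cell:
        numerator, denominator = a * d, b * c
        if numerator == 0 and denominator == 0:
            raw = float("nan")
        elif denominator == 0:
            raw = float("inf")
        else:
            raw = numerator / denominator
        return OddsRatioResult(
            or_estimate=raw, log_or=float("nan"), se_log_or=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), alpha=alpha,
            estimable=False, zero_cell=True,
        )
    estimate = (a * d) / (b * c)
    log_or = math.log(estimate)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        or_estimate=estimate, log_or=log_or, se_log_or=se,
        ci_low=math.exp(log_or - z * se), ci_high=math.exp(log_or + z * se),
        alpha=alpha, estimable=True, zero_cell=False,
    )


def _as_counts(table) -> np.ndarray:
    if isinstance(table, TwoByTwoTable):
        return table.as_array()
    return np.asarray(table, dtype=float)


def pearson_chi2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table or r x c count array, without
    continuity correction.  Raises on a degenerate (all-zero) margin."""
    observed = _as_counts(table)
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    statistic, p, df, _ = stats.chi2_contingency(observed, correction=False)
    return ChiSquareResult(float(statistic), int(df), float(p), "pearson")


def fisher_exact(table: TwoByTwoTable) -> ChiSquareResult:
    """Two-sided Fisher exact test (probability-mass rule): p is the sum
    of hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's."""
    observed = _as_counts(table)
    _, p = stats.fisher_exact(observed, alternative="two-sided")
    return ChiSquareResult(None, 1, float(p), "fisher")


def association_test(
    table: TwoByTwoTable, expected_threshold: float = 5.0
) -> ChiSquareResult:
    """Decision rule used for every contingency p in the reports: Fisher
    when any cell is zero or any expected count is below the threshold,
    Pearson otherwise."""
    observed = _as_counts(table)
    if (observed == 0).any():
        return fisher_exact(table)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    if (expected < expected_threshold).any():
        return fisher_exact(table)
    return pearson_chi2(table)


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    result = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(result.pvalue)


def hwe_test(genotype_counts: Sequence[int]) -> HWEResult:
    """Hardy-Weinberg chi-square goodness of fit on (n_AA, n_Aa, n_aa).

    The allele frequency is the sample MLE p = (2 n_AA + n_Aa) / 2N and
    the expected counts are (p^2, 2pq, q^2) N, compared by a Pearson
    statistic on 1 degree of freedom.  A monomorphic sample is flagged
    degenerate with p = 1.
    """
    n_aa, n_ab, n_bb = (int(x) for x in genotype_counts)
    total = n_aa + n_ab + n_bb
    if total <= 0:
        raise ValueError("empty genotype sample")
    p = (2 * n_aa + n_ab) / (2 * total)
    q = 1 - p
    expected = (p * p * total, 2 * p * q * total, q * q * total)
    if p in (0.0, 1.0):
        return HWEResult(p, expected, 0.0, 1, 1.0, degenerate=True)
    chi2 = sum(
        (obs - exp) ** 2 / exp
        for obs, exp in zip((n_aa, n_ab, n_bb), expected)
    )
    return HWEResult(p, expected, float(chi2), 1, float(stats.chi2.sf(chi2, 1)))


def genetic_model_table(
    counts: GenotypeCountTable, spec: GeneticModelSpec
) -> TwoByTwoTable:
    """Collapse three-genotype counts to the 2x2 of the requested model.

    For GSTP1 (classes AA/AG/GG, risk allele G) the recessive model
    contrasts GG vs AA+AG and the dominant model AG+GG vs AA.  The
    additive model has no 2x2 representation and is rejected here.
    """
    if spec.model == "additive":
        raise ValueError(
            "additive model is a dosage regression; use per_allele_logistic"
        )
    if len(counts.classes) != 3:
        raise ValueError("genetic models need a three-genotype locus")
    hom_wild, het, hom_var = counts.classes
    case = dict(zip(counts.classes, counts.group_counts("case")))
    control = dict(zip(counts.classes, counts.group_counts("control")))
    if spec.model == "recessive":
        variant_side, wild_side = (hom_var,), (hom_wild, het)
        label = f"{hom_var} (recessive)"
    else:
        variant_side, wild_side = (het, hom_var), (hom_wild,)
        label = f"{het}+{hom_var} (dominant)"
    variant = (sum(case[c] for c in variant_side), sum(control[c] for c in variant_side))
    wild = (sum(case[c] for c in wild_side), sum(control[c] for c in wild_side))
    if spec.exposure_orientation == "variant_as_exposure":
        a, b, c, d = variant[0], variant[1], wild[0], wild[1]
    else:
        a, b, c, d = wild[0], wild[1], variant[0], variant[1]
        label = f"not {label}"
    return TwoByTwoTable(a, b, c, d, exposure_label=label)


def allele_table(counts: GenotypeCountTable) -> TwoByTwoTable:
    """Allele-level 2x2 (2N alleles per group): reference allele count
    2*hom_wild + het as exposure, variant allele as the complement."""
    if len(counts.classes) != 3:
        raise ValueError("allele table needs a three-genotype locus")
    case = counts.group_counts("case")
    control = counts.group_counts("control")
    ref_case, ref_control = 2 * case[0] + case[1], 2 * control[0] + control[1]
    var_case, var_control = 2 * case[2] + case[1], 2 * control[2] + control[1]
    return TwoByTwoTable(
        ref_case, ref_control, var_case, var_control,
        exposure_label=f"{counts.classes[0][0]} allele",
    )


def per_allele_logistic(
    counts: GenotypeCountTable, alpha: float = 0.05
) -> OddsRatioResult:
    """Additive genetic model: logistic regression of case status on
    risk-allele dosage 0/1/2, fitted by maximum likelihood (IRLS) on the
    grouped genotype counts.  Returns exp(beta) with a Wald CI.

    Perfect separation (a dosage level with cases or controls only at an
    extreme) is reported as an inestimable result, not an exception.
    """
    if len(counts.classes) != 3:
        raise ValueError("per-allele model needs a three-genotype locus")
    cases = np.array(counts.group_counts("case"), dtype=float)
    controls = np.array(counts.group_counts("control"), dtype=float)
    dosage = np.array([0.0, 1.0, 2.0])
    informative = cases + controls > 0  # empty classes carry no likelihood
    endog = np.column_stack([cases[informative], controls[informative]])
    exog = sm.add_constant(dosage[informative])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        # IRLS converges on the deviance; tol matches the package-wide
        # 1e-10 stopping rule for this fit.
        fit = model.fit(maxiter=50, tol=1e-10)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:  # separation or degenerate counts
        beta, se = float("nan"), float("nan")
    if not (math.isfinite(beta) and math.isfinite(se)) or abs(beta) > 30 or se > 1e3:
        return OddsRatioResult(
            or_estimate=float("nan"), log_or=float("nan"),
            se_log_or=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), alpha=alpha, estimable=False,
            zero_cell=bool((cases == 0).any() or (controls == 0).any()),
        )
    z = stats.norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        or_estimate=math.exp(beta), log_or=beta, se_log_or=se,
        ci_low=math.exp(beta - z * se), ci_high=math.exp(beta + z * se),
        alpha=alpha, estimable=True, zero_cell=False,
    )
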