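"""Odds ratios, contingency tests, HWE and the genetic-model fits.

Independent oracles used here: exhaustive hypergeometric enumeration
(Fisher), the closed-form 2x2 chi-square, numeric quadrature of the t
density (Welch test), and a grid-search maximiser of the grouped
binomial log-likelihood (per-allele logistic).
"""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from gstassoc import (
    GeneticModelSpec,
    GenotypeCountTable,
    TwoByTwoTable,
    allele_table,
    association_test,
    fisher_exact,
    genetic_model_table,
    hwe_test,
    odds_ratio,
    pearson_chi2,
    per_allele_logistic,
    t_test_from_summary,
)

cells = st.integers(min_value=1, max_value=60)


def make_counts(case, control, classes=("AA", "AG", "GG")):
    counts = {("case", c): n for c, n in zip(classes, case)}
    counts.update({("control", c): n for c, n in zip(classes, control)})
    return GenotypeCountTable("gstp1", tuple(classes), counts,
                              {"case": 0, "control": 0})


# ---------------------------------------------------------------------------
# Odds ratio


def test_odds_ratio_published_gstm1_value():
    result = odds_ratio(TwoByTwoTable(34, 53, 70, 51))
    assert math.isclose(result.or_estimate, (34 * 51) / (53 * 70))
    assert result.or_estimate == pytest.approx(0.467, abs=5e-4)
    # published as 0.46 (0.26-0.82); agreement within one printed unit
    assert abs(result.or_estimate - 0.46) <= 0.01
    assert abs(result.ci_low - 0.26) <= 0.01
    assert abs(result.ci_high - 0.82) <= 0.01


def test_odds_ratio_identity_table_symmetric_ci():
    result = odds_ratio(TwoByTwoTable(7, 7, 7, 7))
    assert result.or_estimate == 1.0
    assert math.isclose(result.ci_low * result.ci_high, 1.0, rel_tol=1e-12)


def test_odds_ratio_zero_cell_inestimable():
    result = odds_ratio(TwoByTwoTable(2, 0, 32, 53))
    assert not result.estimable and result.zero_cell
    assert result.or_estimate == math.inf
    zero = odds_ratio(TwoByTwoTable(0, 1, 32, 53))
    assert zero.or_estimate == 0.0 and not zero.estimable


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=cells, b=cells, c=cells, d=cells)
def test_odds_ratio_exposure_swap_reciprocity(a, b, c, d):
    table = TwoByTwoTable(a, b, c, d)
    forward = odds_ratio(table).or_estimate
    backward = odds_ratio(table.swapped()).or_estimate
    assert math.isclose(forward * backward, 1.0, rel_tol=1e-12)


# ---------------------------------------------------------------------------
# Pearson chi-square


@pytest.mark.parametrize(
    "table, expected_stat",
    [((69, 50, 32, 53), 8.2), ((38, 14, 15, 36), 19.65)],
)
def test_pearson_matches_published_statistics(table, expected_stat):
    result = pearson_chi2(TwoByTwoTable(*table))
    assert result.statistic == pytest.approx(expected_stat, abs=0.05)
    assert result.df == 1


def test_pearson_equal_proportions_zero_statistic():
    result = pearson_chi2(TwoByTwoTable(10, 20, 10, 20))
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_pearson_rejects_degenerate_margin():
    with pytest.raises(ValueError, match="margin"):
        pearson_chi2([[0, 0], [5, 7]])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=cells, b=cells, c=cells, d=cells)
def test_pearson_2x2_closed_form(a, b, c, d):
    n = a + b + c + d
    closed = (
        n * (a * d - b * c) ** 2
        / ((a + b) * (c + d) * (a + c) * (b + d))
    )
    result = pearson_chi2(TwoByTwoTable(a, b, c, d))
    assert result.statistic == pytest.approx(closed, rel=1e-10)


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided p by direct enumeration over all tables with the
    observed margins (probability-mass rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    prob = {
        x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)
    }
    observed = prob[a]
    return sum(p for p in prob.values() if p <= observed * (1 + 1e-9))


@pytest.mark.parametrize(
    "table, expected_p",
    [((2, 0, 32, 53), 0.15), ((3, 0, 51, 66), 0.088), ((1, 1, 1, 1), 1.0)],
)
def test_fisher_published_and_trivial_values(table, expected_p):
    result = fisher_exact(TwoByTwoTable(*table))
    assert result.p_value == pytest.approx(expected_p, abs=5e-4)
    assert result.statistic is None and result.df == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.integers(0, 30), b=st.integers(0, 30),
    c=st.integers(0, 30), d=st.integers(0, 30),
)
def test_fisher_equals_enumeration_oracle(a, b, c, d):
    if a + b + c + d == 0:
        return
    result = fisher_exact(TwoByTwoTable(a, b, c, d))
    assert result.p_value == pytest.approx(
        fisher_enumeration_oracle(a, b, c, d), rel=1e-8, abs=1e-12
    )


def test_association_test_decision_rule():
    assert association_test(TwoByTwoTable(2, 0, 32, 53)).method == "fisher"
    assert association_test(TwoByTwoTable(2, 3, 4, 5)).method == "fisher"
    assert association_test(TwoByTwoTable(34, 53, 70, 51)).method == "pearson"


# ---------------------------------------------------------------------------
# t-test from summary statistics


def t_tail_quadrature(t_stat, df):
    """P(T > t) by numeric integration of the t density."""
    def pdf(x):
        return (
            special.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * special.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )
    tail, _ = integrate.quad(pdf, abs(t_stat), np.inf)
    return tail


def test_t_test_published_age_comparison():
    p = t_test_from_summary(43.8, 15.1, 104, 44.99, 15.57, 104)
    assert abs(p - 0.57) <= 0.01


def test_t_test_identical_summaries():
    assert t_test_from_summary(5, 2, 10, 5, 2, 10) == pytest.approx(1.0)


def test_t_test_matches_quadrature_oracle():
    mean1, sd1, n1, mean2, sd2, n2 = 0.0, 1.0, 10, 5.0, 1.0, 10
    p = t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2)
    se = math.sqrt(sd1**2 / n1 + sd2**2 / n2)
    t_stat = (mean1 - mean2) / se
    df = (sd1**2 / n1 + sd2**2 / n2) ** 2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    assert p == pytest.approx(2 * t_tail_quadrature(t_stat, df), rel=1e-6)


def test_t_test_invalid_inputs():
    with pytest.raises(ValueError):
        t_test_from_summary(1, 1, 1, 2, 1, 10)
    with pytest.raises(ValueError):
        t_test_from_summary(1, 0, 10, 2, 1, 10)


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@pytest.mark.parametrize(
    "counts, expected_p",
    [((66, 33, 5), 0.73), ((54, 38, 12), 0.19)],
)
def test_hwe_published_p_values(counts, expected_p):
    result = hwe_test(counts)
    assert abs(result.p_value - expected_p) <= 0.01
    assert sum(result.expected_counts) == pytest.approx(sum(counts))


def test_hwe_exact_equilibrium_counts():
    result = hwe_test((25, 50, 25))
    assert result.chi2 == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_hwe_monomorphic_degenerate():
    result = hwe_test((30, 0, 0))
    assert result.degenerate and result.p_value == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n_aa=st.integers(0, 80), n_ab=st.integers(0, 80), n_bb=st.integers(0, 80)
)
def test_hwe_invariant_to_allele_relabeling(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    forward = hwe_test((n_aa, n_ab, n_bb))
    backward = hwe_test((n_bb, n_ab, n_aa))
    assert forward.chi2 == pytest.approx(backward.chi2, abs=1e-9)


# ---------------------------------------------------------------------------
# Genetic models and allele table


def test_recessive_and_dominant_collapse(gstp1_counts):
    recessive = genetic_model_table(
        gstp1_counts, GeneticModelSpec("recessive")
    )
    assert (recessive.a, recessive.b, recessive.c, recessive.d) == (92, 99, 12, 5)
    assert abs(odds_ratio(recessive).or_estimate - 0.38) <= 0.01
    dominant = genetic_model_table(gstp1_counts, GeneticModelSpec("dominant"))
    assert (dominant.a, dominant.b, dominant.c, dominant.d) == (54, 66, 50, 38)
    assert abs(odds_ratio(dominant).or_estimate - 0.62) <= 0.01


def test_variant_orientation_inverts_or(gstp1_counts):
    wild = genetic_model_table(gstp1_counts, GeneticModelSpec("recessive"))
    variant = genetic_model_table(
        gstp1_counts,
        GeneticModelSpec("recessive", exposure_orientation="variant_as_exposure"),
    )
    product = odds_ratio(wild).or_estimate * odds_ratio(variant).or_estimate
    assert math.isclose(product, 1.0, rel_tol=1e-12)


def test_additive_model_rejected_by_table_collapse(gstp1_counts):
    with pytest.raises(ValueError, match="per_allele_logistic"):
        genetic_model_table(gstp1_counts, GeneticModelSpec("additive"))


def test_recessive_with_empty_class_flags_inestimable():
    counts = make_counts((10, 5, 0), (8, 7, 2))
    table = genetic_model_table(counts, GeneticModelSpec("recessive"))
    assert not odds_ratio(table).estimable


def test_allele_table_published_counts(gstp1_counts):
    table = allele_table(gstp1_counts)
    assert (table.a, table.b, table.c, table.d) == (146, 165, 62, 43)
    assert abs(odds_ratio(table).or_estimate - 0.61) <= 0.01


def test_allele_table_trivial_cases():
    all_aa = make_counts((10, 0, 0), (8, 0, 0))
    table = allele_table(all_aa)
    assert table.c == 0 and table.d == 0
    uniform = make_counts((1, 1, 1), (1, 1, 1))
    assert odds_ratio(allele_table(uniform)).or_estimate == 1.0


# ---------------------------------------------------------------------------
# Per-allele logistic


def grid_search_mle(cases, controls, span=4.0, steps=601):
    """Brute-force maximiser of the grouped binomial log-likelihood of
    logit P(case) = alpha + beta * dosage over an (alpha, beta) grid,
    refined around the best point until the grid pitch is ~1e-6."""
    dosage = np.array([0.0, 1.0, 2.0])
    cases = np.asarray(cases, float)
    controls = np.asarray(controls, float)

    center_a, center_b, width = 0.0, 0.0, span
    for _ in range(5):
        alphas = np.linspace(center_a - width, center_a + width, steps)
        betas = np.linspace(center_b - width, center_b + width, steps)
        grid_a, grid_b = np.meshgrid(alphas, betas, indexing="ij")
        eta = grid_a[..., None] + grid_b[..., None] * dosage
        loglik = np.sum(
            cases * eta - (cases + controls) * np.logaddexp(0, eta), axis=-1
        )
        i, j = np.unravel_index(np.argmax(loglik), loglik.shape)
        center_a, center_b = alphas[i], betas[j]
        width /= steps / 8
    return center_b


def test_per_allele_logistic_published_estimate(gstp1_counts):
    result = per_allele_logistic(gstp1_counts)
    assert result.or_estimate == pytest.approx(1.569, abs=5e-4)
    assert result.ci_low == pytest.approx(1.016, abs=5e-3)
    assert result.ci_high == pytest.approx(2.423, abs=5e-3)


def test_per_allele_logistic_null_distribution():
    counts = make_counts((20, 30, 10), (20, 30, 10))
    result = per_allele_logistic(counts)
    assert result.or_estimate == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize(
    "cases, controls",
    [((54, 38, 12), (66, 33, 5)), ((5, 9, 11), (12, 7, 3))],
)
def test_per_allele_logistic_matches_grid_oracle(cases, controls):
    result = per_allele_logistic(make_counts(cases, controls))
    assert result.log_or == pytest.approx(
        grid_search_mle(cases, controls), abs=1e-4
    )


def test_per_allele_logistic_het_empty_reduces_to_2x2_or():
    # With no heterozygotes the dosage covariate is binary (gap 2), so
    # exp(2 beta) must equal the hom-hom cross-product odds ratio.
    cases, controls = (20, 0, 10), (30, 0, 5)
    result = per_allele_logistic(make_counts(cases, controls))
    cross_product = (10 * 30) / (5 * 20)
    assert math.exp(2 * result.log_or) == pytest.approx(cross_product, rel=1e-6)


def test_per_allele_logistic_separation_flagged():
    counts = make_counts((0, 0, 10), (10, 5, 0))
    result = per_allele_logistic(counts)
    assert not result.estimable
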