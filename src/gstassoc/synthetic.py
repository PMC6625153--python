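"""Synthetic subject-level cohorts.

Two modes:

* **Fixture mode** (:func:`generate_fixture`) reconstructs record sets
  whose aggregated margins equal the published study tables
  cell-for-cell.  The published tables constrain only margins, so the
  builder solves a small integer margin-completion problem: for each
  group the joint (GSTM1, GSTT1, GSTP1-carrier, smoking) distribution
  must match six pairwise 2x2 margins at once.  A joint solution exists
  for the demographic, single-locus, gene-gene and gene-smoking tables
  simultaneously ("paper-all"); the two treatment-response blocks are
  mutually inconsistent (their responder totals over the same 104 cases
  differ), so the GSTP1 response block is emitted as its own record set
  and the manifest says so.

* **Model mode** (:func:`generate_cohort`) simulates case-control
  cohorts by retrospective tilting: controls are drawn from configured
  exposure-profile frequencies (GSTP1 genotypes under Hardy-Weinberg
  proportions), cases from P(profile | case) proportional to
  P(profile | control) x OR(profile), where OR(profile) multiplies the
  configured main-effect and pairwise-interaction odds multipliers.
  This makes the configured odds ratios exactly the estimands of the
  downstream analysis.  :func:`attach_survival` adds response and
  survival fields from per-genotype exponential event processes with
  uniform censoring.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Optional

import numpy as np

from . import _tables
from .cohort import SubjectRecord

__all__ = [
    "FixtureSpec",
    "SimulationConfig",
    "SurvivalConfig",
    "generate_fixture",
    "fixture_manifest",
    "generate_cohort",
    "attach_survival",
    "FIXTURE_BLOCKS",
    "DEFAULT_EFFECT_ORS",
]

# ---------------------------------------------------------------------------
# Fixture mode

FIXTURE_BLOCKS = (
    "table1",
    "gstm1", "gstt1", "gstp1",
    "gstm1_gstt1", "gstm1_gstp1", "gstt1_gstp1",
    "gstm1_smoking", "gstt1_smoking", "gstp1_smoking",
    "table5_gstm1", "table5_gstp1",
    "paper-all",
)

_LEVELS = {
    "gstm1": {1: "null", 0: "present"},
    "gstt1": {1: "null", 0: "present"},
    "smoking": {1: "smoker", 0: "nonsmoker"},
}


@dataclass(frozen=True)
class FixtureSpec:
    """A named published-table block with (optionally overridden) cell
    counts, validated against the group sizes."""

    name: str
    counts: Optional[dict] = None
    n_cases: int = 104
    n_controls: int = 104


def _pair_counts(name: str) -> dict:
    if name in _tables.GENE_GENE:
        return _tables.GENE_GENE[name]
    if name in _tables.GENE_SMOKING:
        return _tables.GENE_SMOKING[name]
    raise KeyError(name)


def _check_group_totals(counts_by_group: dict, sizes: dict, name: str) -> None:
    for group, cells in counts_by_group.items():
        total = sum(cells.values())
        if total > sizes[group]:
            raise ValueError(
                f"fixture {name!r}: {group} counts sum to {total}, "
                f"exceeding group size {sizes[group]}"
            )


def _solve_three_factor(mp: dict, ms: dict, ps: dict, total: int) -> Optional[dict]:
    """Nonnegative integer 2x2x2 joint counts n[(m, p, s)] matching the
    three pairwise margins ``mp[(m,p)]``, ``ms[(m,s)]``, ``ps[(p,s)]``.

    The system has one free parameter x = n[(1,1,1)]; returns the
    solution at the smallest feasible x (deterministic), or None.
    """
    margins_ok = (
        sum(mp.values()) == sum(ms.values()) == sum(ps.values()) == total
        and mp[(1, 1)] + mp[(1, 0)] == ms[(1, 1)] + ms[(1, 0)]
        and mp[(1, 1)] + mp[(0, 1)] == ps[(1, 1)] + ps[(1, 0)]
        and ms[(1, 1)] + ms[(0, 1)] == ps[(1, 1)] + ps[(0, 1)]
    )
    if not margins_ok:
        return None
    for x in range(0, min(mp[(1, 1)], ms[(1, 1)], ps[(1, 1)]) + 1):
        cells = {
            (1, 1, 1): x,
            (1, 1, 0): mp[(1, 1)] - x,
            (1, 0, 1): ms[(1, 1)] - x,
            (1, 0, 0): mp[(1, 0)] - (ms[(1, 1)] - x),
            (0, 1, 1): ps[(1, 1)] - x,
            (0, 1, 0): mp[(0, 1)] - (ps[(1, 1)] - x),
            (0, 0, 1): ms[(0, 1)] - (ps[(1, 1)] - x),
        }
        cells[(0, 0, 0)] = total - sum(cells.values())
        if all(v >= 0 for v in cells.values()):
            return cells
    return None


def _enumerate_small_joint(total: int, m1: int, p1: int, s1: int):
    """All 2x2x2 joint tables with the given *single*-factor exposed
    totals (used for the tiny GSTT1-null stratum; ``total`` <= a few)."""
    cells_keys = list(itertools.product((1, 0), repeat=3))
    for combo in itertools.combinations_with_replacement(range(len(cells_keys)), total):
        counts = {k: 0 for k in cells_keys}
        for index in combo:
            counts[cells_keys[index]] += 1
        if (
            sum(v for (m, p, s), v in counts.items() if m == 1) == m1
            and sum(v for (m, p, s), v in counts.items() if p == 1) == p1
            and sum(v for (m, p, s), v in counts.items() if s == 1) == s1
        ):
            yield counts


def _solve_joint_group(group: str) -> dict:
    """Joint (gstm1, gstt1, gstp1-carrier, smoking) integer counts for
    one group matching all six published pairwise margins."""
    mt = _tables.GENE_GENE["gstm1_gstt1"][group]
    mp = _tables.GENE_GENE["gstm1_gstp1"][group]
    tp = _tables.GENE_GENE["gstt1_gstp1"][group]
    ms = _tables.GENE_SMOKING["gstm1_smoking"][group]
    ts = _tables.GENE_SMOKING["gstt1_smoking"][group]
    ps = _tables.GENE_SMOKING["gstp1_smoking"][group]
    total = sum(mt.values())
    t_null_total = mt[(1, 1)] + mt[(0, 1)]
    # Allocate the (tiny) GSTT1-null stratum, then solve the remaining
    # three-factor system among GSTT1-present subjects.
    for t_null in _enumerate_small_joint(
        t_null_total,
        m1=mt[(1, 1)], p1=tp[(1, 1)], s1=ts[(1, 1)],
    ):
        residual_mp = {
            k: mp[k] - sum(v for (m, p, s), v in t_null.items() if (m, p) == k)
            for k in mp
        }
        residual_ms = {
            k: ms[k] - sum(v for (m, p, s), v in t_null.items() if (m, s) == k)
            for k in ms
        }
        residual_ps = {
            k: ps[k] - sum(v for (m, p, s), v in t_null.items() if (p, s) == k)
            for k in ps
        }
        if any(
            v < 0
            for margin in (residual_mp, residual_ms, residual_ps)
            for v in margin.values()
        ):
            continue
        t_present = _solve_three_factor(
            residual_mp, residual_ms, residual_ps, total - t_null_total
        )
        if t_present is not None:
            joint = {}
            for (m, p, s), v in t_null.items():
                joint[(m, 1, p, s)] = v
            for (m, p, s), v in t_present.items():
                joint[(m, 0, p, s)] = v
            return joint
    raise ValueError(
        f"published pairwise margins for group {group!r} admit no joint "
        "assignment"
    )


def _exact_mean_sd_ages(n: int, mean: float, sd: float) -> np.ndarray:
    """Deterministic age vector with exactly the requested sample mean
    and SD (ddof=1), clipped implicitly by construction (all positive
    for the demographic parameters used here)."""
    if n == 1:
        return np.array([mean])
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    ages = mean + sd * z
    if (ages < 0).any():
        raise ValueError("requested mean/SD imply negative ages")
    return ages


def _attach_demographics(records_by_group: dict) -> None:
    """Fill sex and age in-place to match the demographic margins."""
    for group, records in records_by_group.items():
        n_male = _tables.DEMOGRAPHICS["sex"][group]["male"]
        mean, sd = _tables.DEMOGRAPHICS["age_mean_sd"][group]
        ages = _exact_mean_sd_ages(len(records), mean, sd)
        for i, record in enumerate(records):
            record.sex = "male" if i < n_male else "female"
            record.age = float(ages[i])


def _attach_response_block(cases: list, block: str) -> None:
    """Fill the four binary endpoints in-place per the named response
    block; ``cases`` must already carry the grouping genotype."""
    spec = _tables.RESPONSE[block]
    locus, group_sizes = spec["grouping"]

    def group_of(record: SubjectRecord) -> str:
        value = getattr(record, locus)
        if locus == "gstp1":
            return "AA" if value == "AA" else "variant"
        return value

    for endpoint, per_group in spec.items():
        if endpoint == "grouping":
            continue
        yes_token, no_token = {
            "mcyr_3m": ("yes", "no"),
            "ccyr_6m": ("yes", "no"),
            "bcrabl_3m": ("le10pct", "gt10pct"),
            "bcrabl_6m": ("lt1pct", "ge1pct"),
        }[endpoint]
        assigned = {g: 0 for g in per_group}
        for record in cases:
            g = group_of(record)
            responders = per_group[g][0]
            token = yes_token if assigned[g] < responders else no_token
            assigned[g] += 1
            setattr(record, endpoint, token)


def _joint_fixture() -> list:
    """The 'paper-all' record set: 104 cases + 104 controls jointly
    reproducing the demographic, genotype, gene-gene and gene-smoking
    margins, with the GSTM1 response block attached to the cases."""
    records_by_group = {}
    for group in _tables.GROUPS:
        joint = _solve_joint_group(group)
        gg_quota = _tables.GENOTYPES["gstp1"][group]["GG"]
        records = []
        counter = 0
        assigned_gg = 0
        prefix = "CA" if group == "case" else "CO"
        for (m, t, p, s) in sorted(joint, reverse=True):
            for _ in range(joint[(m, t, p, s)]):
                counter += 1
                if p == 1:
                    genotype = "GG" if assigned_gg < gg_quota else "AG"
                    assigned_gg += p and assigned_gg < gg_quota
                else:
                    genotype = "AA"
                records.append(
                    SubjectRecord(
                        subject_id=f"{prefix}{counter:04d}",
                        group=group,
                        gstm1=_LEVELS["gstm1"][m],
                        gstt1=_LEVELS["gstt1"][t],
                        gstp1=genotype,
                        smoking=_LEVELS["smoking"][s],
                    )
                )
        records_by_group[group] = records
    _attach_demographics(records_by_group)
    _attach_response_block(records_by_group["case"], "table5_gstm1")
    return records_by_group["case"] + records_by_group["control"]


def _block_fixture(spec: FixtureSpec) -> list:
    """A minimal record set reproducing one named table block; fields
    outside the block stay missing."""
    name = spec.name
    sizes = {"case": spec.n_cases, "control": spec.n_controls}
    records: list[SubjectRecord] = []

    def new_record(group: str, **fields) -> SubjectRecord:
        prefix = "CA" if group == "case" else "CO"
        return SubjectRecord(
            subject_id=f"{prefix}{sum(r.group == group for r in records) + 1:04d}",
            group=group, **fields,
        )

    if name == "table1":
        records_by_group = {}
        for group in _tables.GROUPS:
            smoking = _tables.DEMOGRAPHICS["smoking"][group]
            group_records = []
            for token, count in smoking.items():
                for _ in range(count):
                    group_records.append(
                        SubjectRecord(
                            subject_id=f"{'CA' if group == 'case' else 'CO'}"
                                       f"{len(group_records) + 1:04d}",
                            group=group, smoking=token,
                        )
                    )
            records_by_group[group] = group_records
        _attach_demographics(records_by_group)
        return records_by_group["case"] + records_by_group["control"]

    if name in _tables.GENOTYPES:
        counts = spec.counts or _tables.GENOTYPES[name]
        _check_group_totals(counts, sizes, name)
        for group in _tables.GROUPS:
            for genotype, count in counts[group].items():
                for _ in range(count):
                    records.append(new_record(group, **{name: genotype}))
        return records

    if name in _tables.GENE_GENE or name in _tables.GENE_SMOKING:
        counts = spec.counts or _pair_counts(name)
        _check_group_totals(counts, sizes, name)
        field1, field2 = name.split("_")

        def token(fieldname: str, level: int) -> str:
            if fieldname == "gstp1":
                return "AG" if level else "AA"  # carrier coded as AG
            return _LEVELS[fieldname][level]

        for group in _tables.GROUPS:
            for (l1, l2), count in counts[group].items():
                for _ in range(count):
                    records.append(
                        new_record(
                            group,
                            **{field1: token(field1, l1), field2: token(field2, l2)},
                        )
                    )
        return records

    if name in _tables.RESPONSE:
        locus, group_sizes = _tables.RESPONSE[name]["grouping"]
        cases = []
        for label, count in group_sizes.items():
            genotype = {"variant": "AG", "AA": "AA"}.get(label, label)
            for _ in range(count):
                cases.append(
                    SubjectRecord(
                        subject_id=f"CA{len(cases) + 1:04d}",
                        group="case", **{locus: genotype},
                    )
                )
        _attach_response_block(cases, name)
        return cases

    raise ValueError(f"unknown fixture block {name!r}; known: {FIXTURE_BLOCKS}")


def generate_fixture(spec="paper-all") -> list:
    """Records whose aggregation reproduces the requested published
    table block(s) cell-for-cell.

    ``spec`` is a block name (see :data:`FIXTURE_BLOCKS`) or a
    :class:`FixtureSpec` with custom counts.  ``"paper-all"`` returns
    the joint 208-subject set consistent with the demographic,
    single-locus, gene-gene and gene-smoking tables at once (plus the
    GSTM1 response block); the GSTP1 response block cannot be joint
    with it and has its own block (see :func:`fixture_manifest`).
    """
    if isinstance(spec, str):
        spec = FixtureSpec(name=spec)
    if spec.name == "paper-all":
        return _joint_fixture()
    return _block_fixture(spec)


def fixture_manifest(name: str = "paper-all") -> dict:
    """Machine-readable description of what a fixture block reproduces."""
    if name == "paper-all":
        return {
            "mode": "fixture",
            "block": "paper-all",
            "n_records": 208,
            "reproduces": [
                "table1", "gstm1", "gstt1", "gstp1",
                "gstm1_gstt1", "gstm1_gstp1", "gstt1_gstp1",
                "gstm1_smoking", "gstt1_smoking", "gstp1_smoking",
                "table5_gstm1",
            ],
            "excluded": {
                "table5_gstp1": (
                    "the two response blocks are mutually inconsistent "
                    "(responder totals over the same cases differ); "
                    "generate_fixture('table5_gstp1') emits its own set"
                ),
            },
        }
    return {"mode": "fixture", "block": name, "reproduces": [name]}


# ---------------------------------------------------------------------------
# Model mode

#: Study-condition effect sizes: the published stratified estimates.
#: Keys are main-effect indicators or "a:b" pairwise odds multipliers.
DEFAULT_EFFECT_ORS = {
    "gstm1_null": 2.0757,
    "smoking": 2.6824,
    "gstm1_null:smoking": 6.5143 / (2.0757 * 2.6824),
    "gstp1_g_allele": 1.569,
}

_TERM_NAMES = (
    "gstm1_null", "gstt1_null", "gstp1_variant", "gstp1_g_allele", "smoking",
)


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential event-time model for the case group.

    ``response_hazard_by_gstm1``: per-month hazard of achieving the
    molecular response, by GSTM1 genotype; ``efs_hazard``: per-month
    hazard of the composite EFS event (shared across genotypes by
    default); censoring is uniform on (0, horizon]."""

    response_hazard_by_gstm1: dict = dc_field(
        default_factory=lambda: {"null": 0.02, "present": 0.06}
    )
    efs_hazard_by_gstm1: dict = dc_field(
        default_factory=lambda: {"null": 0.005, "present": 0.005}
    )
    horizon_months: float = 72.0

    def __post_init__(self) -> None:
        hazards = list(self.response_hazard_by_gstm1.values()) + list(
            self.efs_hazard_by_gstm1.values()
        )
        if any(h < 0 for h in hazards):
            raise ValueError("hazards must be nonnegative")
        if self.horizon_months <= 0:
            raise ValueError("horizon must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated case-control cohort.

    Defaults are the published cohort's margins: 104 subjects per arm,
    control exposure frequencies from the control column of the
    demographic and genotype tables, and effect odds ratios from the
    published stratified estimates.
    """

    n_cases: int = 104
    n_controls: int = 104
    control_gstm1_null_freq: float = 51 / 104
    control_gstt1_null_freq: float = 1 / 104
    control_gstp1_g_allele_freq: float = 43 / 208
    control_smoking_prev: float = 31 / 104
    effect_ors: dict = dc_field(default_factory=lambda: dict(DEFAULT_EFFECT_ORS))
    male_prob: dict = dc_field(
        default_factory=lambda: {"case": 55 / 104, "control": 57 / 104}
    )
    age_mean_sd: dict = dc_field(
        default_factory=lambda: {"case": (43.8, 15.1), "control": (44.99, 15.57)}
    )
    survival: Optional[SurvivalConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "control_gstm1_null_freq", "control_gstt1_null_freq",
            "control_gstp1_g_allele_freq", "control_smoking_prev",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be a probability")
        for term, value in self.effect_ors.items():
            if value <= 0:
                raise ValueError(f"effect OR for {term!r} must be positive")
            parts = term.split(":")
            if not all(p in _TERM_NAMES for p in parts) or len(parts) > 2:
                raise ValueError(f"unknown effect term {term!r}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("arm sizes must be positive")


def _profiles(config: SimulationConfig):
    """All 24 exposure profiles with control probabilities and odds
    multipliers."""
    q = config.control_gstp1_g_allele_freq
    hwe = {"AA": (1 - q) ** 2, "AG": 2 * q * (1 - q), "GG": q * q}
    dosage = {"AA": 0, "AG": 1, "GG": 2}
    profiles, probs, multipliers = [], [], []
    for m in ("null", "present"):
        p_m = (
            config.control_gstm1_null_freq
            if m == "null" else 1 - config.control_gstm1_null_freq
        )
        for t in ("null", "present"):
            p_t = (
                config.control_gstt1_null_freq
                if t == "null" else 1 - config.control_gstt1_null_freq
            )
            for genotype in ("AA", "AG", "GG"):
                for s in ("smoker", "nonsmoker"):
                    p_s = (
                        config.control_smoking_prev
                        if s == "smoker" else 1 - config.control_smoking_prev
                    )
                    indicator = {
                        "gstm1_null": m == "null",
                        "gstt1_null": t == "null",
                        "gstp1_variant": genotype != "AA",
                        "smoking": s == "smoker",
                    }
                    multiplier = 1.0
                    for term, value in config.effect_ors.items():
                        parts = term.split(":")
                        if parts == ["gstp1_g_allele"]:
                            multiplier *= value ** dosage[genotype]
                        elif len(parts) == 1:
                            multiplier *= value if indicator[parts[0]] else 1.0
                        else:
                            active = all(
                                indicator.get(p, dosage[genotype] > 0 if
                                              p == "gstp1_g_allele" else False)
                                for p in parts
                            )
                            multiplier *= value if active else 1.0
                    profiles.append((m, t, genotype, s))
                    probs.append(p_m * p_t * hwe[genotype] * p_s)
                    multipliers.append(multiplier)
    probs = np.asarray(probs)
    multipliers = np.asarray(multipliers)
    return profiles, probs / probs.sum(), multipliers


def generate_cohort(config: SimulationConfig) -> list:
    """Simulate a case-control cohort under the retrospective tilt
    model; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    profiles, control_probs, multipliers = _profiles(config)
    case_probs = control_probs * multipliers
    case_probs = case_probs / case_probs.sum()
    records = []
    for group, n, probs in (
        ("case", config.n_cases, case_probs),
        ("control", config.n_controls, control_probs),
    ):
        draws = rng.choice(len(profiles), size=n, p=probs)
        sexes = rng.random(n) < config.male_prob[group]
        mean, sd = config.age_mean_sd[group]
        ages = np.clip(rng.normal(mean, sd, size=n), 0.0, None)
        prefix = "SC" if group == "case" else "SN"
        for i, (index, male, age) in enumerate(zip(draws, sexes, ages), start=1):
            m, t, genotype, s = profiles[index]
            records.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i:06d}", group=group,
                    gstm1=m, gstt1=t, gstp1=genotype, smoking=s,
                    sex="male" if male else "female", age=float(age),
                )
            )
    return records


def attach_survival(
    records: Iterable[SubjectRecord],
    config: SurvivalConfig,
    seed: int = 0,
) -> list:
    """Return copies of the case records with response/survival fields.

    A response-time process R ~ Exponential(hazard by GSTM1 genotype)
    drives both the binary 3/6-month endpoints (responder iff R <= 3 or
    R <= 6 months respectively) and the censored time-to-MMR; an
    independent EFS process uses its own hazards.  Censoring times are
    uniform on (0, horizon].  Zero hazard means no events (everything
    censored).  Non-case records pass through unchanged.
    """
    rng = np.random.default_rng(seed)
    out = []
    for record in records:
        if record.group != "case":
            out.append(record)
            continue
        genotype = record.gstm1 if record.gstm1 is not None else "present"
        response_hazard = config.response_hazard_by_gstm1[genotype]
        efs_hazard = config.efs_hazard_by_gstm1[genotype]
        response_time = (
            rng.exponential(1 / response_hazard)
            if response_hazard > 0 else math.inf
        )
        efs_time = (
            rng.exponential(1 / efs_hazard) if efs_hazard > 0 else math.inf
        )
        censor_response = rng.uniform(0, config.horizon_months)
        censor_efs = rng.uniform(0, config.horizon_months)
        mmr_event = response_time <= censor_response
        efs_event = efs_time <= censor_efs
        out.append(
            replace(
                record,
                mcyr_3m="yes" if response_time <= 3 else "no",
                ccyr_6m="yes" if response_time <= 6 else "no",
                bcrabl_3m="le10pct" if response_time <= 3 else "gt10pct",
                bcrabl_6m="lt1pct" if response_time <= 6 else "ge1pct",
                mmr_time=float(response_time if mmr_event else censor_response),
                mmr_event="yes" if mmr_event else "no",
                efs_time=float(efs_time if efs_event else censor_efs),
                efs_event="yes" if efs_event else "no",
            )
        )
    return out
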