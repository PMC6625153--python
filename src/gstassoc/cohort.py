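"""Subject-level data model, cohort file I/O and count aggregation.

A cohort is a flat delimited-text table (comma by default, any single
character accepted), one row per subject, with lower-case category
tokens and missing values encoded as an empty cell or ``NA``.  The
column dictionary is documented in ``docs/cohort_format.md``.

Everything downstream (odds ratios, interaction measures, response and
survival endpoints) consumes either :class:`TwoByTwoTable` or
:class:`GenotypeCountTable` objects built here; exclusion of records
with missing values is per-analysis (complete-case), never global.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("gstassoc")

__all__ = [
    "SubjectRecord",
    "TwoByTwoTable",
    "GenotypeCountTable",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "aggregate_2x2",
    "genotype_counts",
    "cohort_summary",
    "field_equals",
    "is_case",
    "gstm1_null",
    "gstm1_present",
    "gstt1_null",
    "gstt1_present",
    "gstp1_variant",
    "gstp1_aa",
    "smoker",
]

#: Allowed tokens per categorical field (canonical in-memory spelling).
CATEGORICAL_FIELDS: dict[str, tuple[str, ...]] = {
    "group": ("case", "control"),
    "gstm1": ("present", "null"),
    "gstt1": ("present", "null"),
    "gstp1": ("AA", "AG", "GG"),
    "smoking": ("smoker", "nonsmoker"),
    "sex": ("male", "female"),
    "mcyr_3m": ("yes", "no"),
    "ccyr_6m": ("yes", "no"),
    "bcrabl_3m": ("le10pct", "gt10pct"),
    "bcrabl_6m": ("lt1pct", "ge1pct"),
    "mmr_event": ("yes", "no"),
    "efs_event": ("yes", "no"),
}

NUMERIC_FIELDS = ("age", "mmr_time", "efs_time")

#: Canonical column order of the cohort file.
COLUMNS = (
    "subject_id", "group", "gstm1", "gstt1", "gstp1", "smoking", "sex",
    "age", "mcyr_3m", "ccyr_6m", "bcrabl_3m", "bcrabl_6m",
    "mmr_time", "mmr_event", "efs_time", "efs_event",
)

MISSING_TOKENS = ("", "na")


@dataclass
class SubjectRecord:
    """One study participant.  ``None`` encodes a missing value; ``group``
    is mandatory.  Validation happens at construction time."""

    subject_id: str
    group: str
    gstm1: Optional[str] = None
    gstt1: Optional[str] = None
    gstp1: Optional[str] = None
    smoking: Optional[str] = None
    sex: Optional[str] = None
    age: Optional[float] = None
    mcyr_3m: Optional[str] = None
    ccyr_6m: Optional[str] = None
    bcrabl_3m: Optional[str] = None
    bcrabl_6m: Optional[str] = None
    mmr_time: Optional[float] = None
    mmr_event: Optional[str] = None
    efs_time: Optional[float] = None
    efs_event: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be nonempty")
        for name, allowed in CATEGORICAL_FIELDS.items():
            value = getattr(self, name)
            if name == "group" and value is None:
                raise ValueError("group is required (case/control)")
            if value is not None and value not in allowed:
                raise ValueError(
                    f"invalid token {value!r} for field {name!r}; "
                    f"allowed: {', '.join(allowed)}"
                )
        for name in NUMERIC_FIELDS:
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be a nonnegative finite number")
        if self.mmr_event == "yes" and self.mmr_time is None:
            raise ValueError("mmr_event=yes requires mmr_time")
        if self.efs_event == "yes" and self.efs_time is None:
            raise ValueError("efs_event=yes requires efs_time")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Labeled 2x2 count table: ``a``/``b`` exposed cases/controls,
    ``c``/``d`` unexposed cases/controls."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    outcome_label: str = "case"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("2x2 cells must be nonnegative integers")
        if self.total < 1:
            raise ValueError("2x2 table must contain at least one subject")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped(self) -> "TwoByTwoTable":
        """Same table with the exposure dichotomy inverted."""
        return TwoByTwoTable(
            self.c, self.d, self.a, self.b,
            exposure_label=f"not {self.exposure_label}",
            outcome_label=self.outcome_label,
            n_excluded=self.n_excluded,
        )


@dataclass(frozen=True)
class GenotypeCountTable:
    """Per-group genotype class counts at one locus."""

    locus: str
    classes: tuple
    counts: dict  # (group, class) -> count
    n_missing: dict  # group -> count of records with a missing genotype

    def group_counts(self, group: str) -> tuple:
        return tuple(self.counts[(group, cls)] for cls in self.classes)

    def group_total(self, group: str) -> int:
        return sum(self.group_counts(group))


@dataclass(frozen=True)
class CohortSummary:
    """Demographic margins: group sizes, sex and smoking counts and the
    age mean/SD per group (missing values tracked separately)."""

    n: dict
    sex: dict
    smoking: dict
    age_mean_sd: dict
    age_n_missing: dict
    sex_n_missing: dict
    smoking_n_missing: dict


# ---------------------------------------------------------------------------
# File I/O


def _parse_cell(row_num: int, column: str, token: str):
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    if column in NUMERIC_FIELDS:
        try:
            return float(token)
        except ValueError:
            raise ValueError(
                f"row {row_num}, column {column!r}: not a number: {token!r}"
            ) from None
    allowed = CATEGORICAL_FIELDS[column]
    canonical = {t.lower(): t for t in allowed}
    if token.lower() not in canonical:
        raise ValueError(
            f"row {row_num}, column {column!r}: unknown category token "
            f"{token!r}; allowed: {', '.join(t.lower() for t in allowed)}"
        )
    return canonical[token.lower()]


def read_cohort(path, delimiter: str = ",") -> list[SubjectRecord]:
    """Read a cohort file into validated :class:`SubjectRecord` objects.

    Unknown columns are preserved verbatim in ``record.extras``; empty
    cells and ``NA`` map to missing; category tokens are matched
    case-insensitively.  Raises ``ValueError`` naming row, column and
    token on any schema violation, and on duplicate subject ids.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("cohort file must have subject_id and group columns")
    known = [c for c in COLUMNS if c in df.columns]
    extra_cols = [c for c in df.columns if c not in COLUMNS]
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        kwargs = {}
        for col in known:
            if col == "subject_id":
                kwargs[col] = data[col].strip()
            else:
                kwargs[col] = _parse_cell(idx, col, data[col])
        kwargs["extras"] = {c: data[c] for c in extra_cols}
        record = SubjectRecord(**kwargs)
        if record.subject_id in seen:
            raise ValueError(f"duplicate subject_id {record.subject_id!r} at row {idx}")
        seen.add(record.subject_id)
        records.append(record)
    if not records:
        logger.warning("cohort file %s has a valid header but no data rows", path)
    logger.info("read %d records from %s", len(records), path)
    return records


def write_cohort(records: Iterable[SubjectRecord], path, delimiter: str = ",") -> None:
    """Write records in the canonical column order (lower-case tokens,
    empty cell for missing); extras appended as additional columns."""
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extras})

    def cell(value) -> str:
        if value is None:
            return ""
        if isinstance(value, float):
            return repr(value)
        return str(value).lower() if not isinstance(value, str) else value.lower()

    rows = []
    for r in records:
        row = {}
        for col in COLUMNS:
            value = getattr(r, col)
            if col == "subject_id":
                row[col] = value
            elif col in NUMERIC_FIELDS:
                row[col] = "" if value is None else repr(float(value))
            else:
                row[col] = cell(value)
        for col in extra_cols:
            row[col] = r.extras.get(col, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(COLUMNS) + extra_cols).to_csv(
        path, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Predicates

Predicate = Callable[[SubjectRecord], Optional[bool]]


def field_equals(name: str, *values: str) -> Predicate:
    """Predicate factory: True when the field equals one of ``values``,
    None when the field is missing (record excluded complete-case)."""

    def predicate(record: SubjectRecord) -> Optional[bool]:
        value = getattr(record, name)
        if value is None:
            return None
        return value in values

    predicate.__name__ = f"{name}_in_{'_'.join(values)}"
    return predicate


is_case = field_equals("group", "case")
gstm1_null = field_equals("gstm1", "null")
gstm1_present = field_equals("gstm1", "present")
gstt1_null = field_equals("gstt1", "null")
gstt1_present = field_equals("gstt1", "present")
gstp1_variant = field_equals("gstp1", "AG", "GG")
gstp1_aa = field_equals("gstp1", "AA")
smoker = field_equals("smoking", "smoker")


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_2x2(
    records: Iterable[SubjectRecord],
    exposure: Predicate,
    outcome: Predicate = is_case,
    exposure_label: str = "exposed",
    outcome_label: str = "case",
) -> TwoByTwoTable:
    """Cross-tabulate exposure x outcome over the complete cases.

    Records for which either predicate returns ``None`` (missing input)
    are excluded and counted in ``n_excluded``.
    """
    a = b = c = d = 0
    excluded = 0
    for record in records:
        e, o = exposure(record), outcome(record)
        if e is None or o is None:
            excluded += 1
            continue
        if e:
            a, b = (a + 1, b) if o else (a, b + 1)
        else:
            c, d = (c + 1, d) if o else (c, d + 1)
    if excluded:
        logger.info("aggregate_2x2: excluded %d records with missing values", excluded)
    return TwoByTwoTable(a, b, c, d, exposure_label, outcome_label, n_excluded=excluded)


def genotype_counts(records: Iterable[SubjectRecord], locus: str) -> GenotypeCountTable:
    """Per-group genotype counts at ``locus`` (gstm1/gstt1/gstp1)."""
    if locus not in ("gstm1", "gstt1", "gstp1"):
        raise ValueError(f"unknown locus {locus!r}")
    classes = CATEGORICAL_FIELDS[locus]
    counts = {(g, cls): 0 for g in ("case", "control") for cls in classes}
    missing = {"case": 0, "control": 0}
    for record in records:
        value = getattr(record, locus)
        if value is None:
            missing[record.group] += 1
        else:
            counts[(record.group, value)] += 1
    return GenotypeCountTable(locus, tuple(classes), counts, missing)


def cohort_summary(records: Iterable[SubjectRecord]) -> CohortSummary:
    """Demographic margins per group (sex, smoking, age mean/SD)."""
    records = list(records)
    n = {g: 0 for g in ("case", "control")}
    sex = {g: {"male": 0, "female": 0} for g in n}
    smoking = {g: {"smoker": 0, "nonsmoker": 0} for g in n}
    ages: dict[str, list[float]] = {g: [] for g in n}
    miss = {k: {g: 0 for g in n} for k in ("sex", "smoking", "age")}
    for r in records:
        n[r.group] += 1
        for fieldname, table in (("sex", sex), ("smoking", smoking)):
            value = getattr(r, fieldname)
            if value is None:
                miss[fieldname][r.group] += 1
            else:
                table[r.group][value] += 1
        if r.age is None:
            miss["age"][r.group] += 1
        else:
            ages[r.group].append(r.age)
    age_mean_sd = {}
    for g, values in ages.items():
        if len(values) >= 2:
            arr = np.asarray(values)
            age_mean_sd[g] = (float(arr.mean()), float(arr.std(ddof=1)))
        elif values:
            age_mean_sd[g] = (float(values[0]), float("nan"))
        else:
            age_mean_sd[g] = (float("nan"), float("nan"))
    return CohortSummary(
        n=n, sex=sex, smoking=smoking, age_mean_sd=age_mean_sd,
        age_n_missing=miss["age"], sex_n_missing=miss["sex"],
        smoking_n_missing=miss["smoking"],
    )
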