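"""Treatment-response and survival endpoints for the case group.

ELN-style binary response categories at 3 and 6 months are tabulated by
genotype grouping and tested with the same Pearson/Fisher decision rule
as the association tables.  Time-to-MMR and event-free survival are
estimated by the Kaplan-Meier product-limit method and two genotype
groups are compared with the log-rank test.  The composite EFS event
(loss of CCyR/MMR, progression to accelerated/blast phase, or death) is
consumed pre-coded — deriving it would require visit-level measurement
schedules that a flat cohort table does not carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as _scipy_stats

from .association import ChiSquareResult, association_test
from .cohort import Predicate, SubjectRecord, TwoByTwoTable

__all__ = [
    "ResponseTable",
    "KMCurve",
    "LogRankResult",
    "ENDPOINT_RESPONDER",
    "response_table",
    "km_estimate",
    "logrank_test",
    "efs_events",
    "mmr_events",
]

#: Token that counts as an (optimal) responder per endpoint.
ENDPOINT_RESPONDER = {
    "mcyr_3m": "yes",
    "ccyr_6m": "yes",
    "bcrabl_3m": "le10pct",
    "bcrabl_6m": "lt1pct",
}


@dataclass(frozen=True)
class ResponseTable:
    """Responder/non-responder 2x2 by genotype grouping (cases only)."""

    genotype_grouping: str
    endpoint: str
    counts: TwoByTwoTable  # a/b: group1 resp/non-resp, c/d: group2
    test: ChiSquareResult
    n_missing: int


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate as a step function.

    ``times`` lists the distinct observed times (events and censorings),
    ``survival`` the estimate just after each time, ``at_risk`` the risk
    set immediately before it, ``events``/``censored`` the per-time
    counts.  S(0-) = 1 implicitly; ties are resolved with events
    preceding censorings at the same time.
    """

    times: tuple
    survival: tuple
    at_risk: tuple
    events: tuple
    censored: tuple
    n_events: int
    n_censored: int

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, value in zip(self.times, self.survival):
            if time <= t:
                s = value
            else:
                break
        return s


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: dict  # group label -> observed events
    expected: dict  # group label -> expected events under H0


def response_table(
    records: Iterable[SubjectRecord],
    grouping: Predicate,
    endpoint: str,
    grouping_label: str = "genotype group",
) -> ResponseTable:
    """Responder counts by genotype group among cases.

    ``grouping`` maps a record to True for the first row of the table
    (e.g. GSTM1 null) and None when the genotype is missing.  Cases with
    a missing endpoint are excluded and counted.
    """
    if endpoint not in ENDPOINT_RESPONDER:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    responder_token = ENDPOINT_RESPONDER[endpoint]
    cells = {(g, r): 0 for g in (1, 0) for r in (1, 0)}
    missing = 0
    any_case = False
    for record in records:
        if record.group != "case":
            continue
        any_case = True
        group_flag = grouping(record)
        value = getattr(record, endpoint)
        if group_flag is None or value is None:
            missing += 1
            continue
        cells[(int(group_flag), int(value == responder_token))] += 1
    if not any_case:
        raise ValueError("response_table needs case records")
    if sum(cells.values()) == 0:
        raise ValueError(f"endpoint {endpoint!r} entirely missing among cases")
    counts = TwoByTwoTable(
        cells[(1, 1)], cells[(1, 0)], cells[(0, 1)], cells[(0, 0)],
        exposure_label=grouping_label, outcome_label=f"{endpoint} responder",
        n_excluded=missing,
    )
    # Responder columns can be degenerate (all yes / all no); the exact
    # test still yields a p-value (= 1) where Pearson is undefined.
    array = counts.as_array()
    if (array.sum(axis=0) == 0).any() or (array.sum(axis=1) == 0).any():
        test = ChiSquareResult(None, 1, 1.0, "fisher")
    else:
        test = association_test(counts)
    return ResponseTable(grouping_label, endpoint, counts, test, missing)


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate; ``events[i]`` False means censored at
    ``times[i]``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    table = fitter.event_table
    out_times, survival, at_risk, n_events, n_censored = [], [], [], [], []
    for t, row in table.iterrows():
        if t == 0 and row["removed"] == 0:
            continue
        out_times.append(float(t))
        at_risk.append(int(row["at_risk"]))
        n_events.append(int(row["observed"]))
        n_censored.append(int(row["censored"]))
        survival.append(float(fitter.predict(t)))
    return KMCurve(
        times=tuple(out_times), survival=tuple(survival),
        at_risk=tuple(at_risk), events=tuple(n_events),
        censored=tuple(n_censored),
        n_events=int(events.sum()), n_censored=int((~events).sum()),
    )


def logrank_test(
    group_labels: Sequence,
    times: Sequence[float],
    events: Sequence[bool],
) -> LogRankResult:
    """Two-group log-rank test (chi-square on 1 df) over pooled event
    times, with per-group observed and expected event counts."""
    labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    unique = sorted(set(labels.tolist()))
    if len(unique) != 2:
        raise ValueError("logrank_test needs exactly two groups")
    mask = labels == unique[0]
    if mask.all() or not mask.any():
        raise ValueError("one group is empty")
    result = _lifelines_logrank(
        times[mask], times[~mask],
        event_observed_A=events[mask], event_observed_B=events[~mask],
    )
    observed = {u: int(events[labels == u].sum()) for u in unique}
    expected = {u: 0.0 for u in unique}
    for t in np.unique(times[events]):
        at_risk = {u: int(((labels == u) & (times >= t)).sum()) for u in unique}
        deaths = int((events & (times == t)).sum())
        n_total = sum(at_risk.values())
        for u in unique:
            expected[u] += deaths * at_risk[u] / n_total
    statistic = float(result.test_statistic)
    return LogRankResult(
        statistic=statistic, df=1,
        p_value=float(_scipy_stats.chi2.sf(statistic, 1)),
        observed=observed, expected=expected,
    )


def _survival_fields(
    records: Iterable[SubjectRecord], time_field: str, event_field: str
) -> tuple[np.ndarray, np.ndarray, int]:
    times, events = [], []
    missing = 0
    for record in records:
        if record.group != "case":
            continue
        time = getattr(record, time_field)
        event = getattr(record, event_field)
        if event == "yes" and time is None:
            raise ValueError(
                f"record {record.subject_id}: {event_field}=yes without "
                f"{time_field}"
            )
        if time is None or event is None:
            missing += 1
            continue
        times.append(time)
        events.append(event == "yes")
    return np.asarray(times, dtype=float), np.asarray(events, dtype=bool), missing


def efs_events(records: Iterable[SubjectRecord]):
    """Validated (times, event flags, n_missing) for event-free survival
    among cases.  The composite event is pre-coded by the data supplier
    or the synthetic generator."""
    return _survival_fields(records, "efs_time", "efs_event")


def mmr_events(records: Iterable[SubjectRecord]):
    """Validated (times, event flags, n_missing) for time to major
    molecular response among cases ('event' = MMR achieved)."""
    return _survival_fields(records, "mmr_time", "mmr_event")
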