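"""Composite kidney outcome derivation and the statistics used to compare groups.

The composite event (MAKE90) is death through day 90, a >25% drop in eGFR at
day 90 relative to the pre-illness reference, or renal replacement therapy
through day 28 / at day 90.  Event timing follows the earliest time-resolved
component; components assessed only at a fixed visit are timed at that visit
(eGFR drop and RRT-at-day-90 at day 90, RRT-through-day-28 at day 28).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort_io import Cohort

HORIZON_DAY = 90
RRT28_DAY = 28
EGFR_DROP_FRACTION = 0.25


@dataclass(frozen=True)
class Make90Outcome:
    """Composite event indicator with its event/censoring day and components."""

    event: bool
    event_day: int
    components: frozenset[str]

    def __post_init__(self) -> None:
        if self.event != bool(self.components):
            raise ValueError("event flag must match non-emptiness of components")
        if not 1 <= self.event_day <= HORIZON_DAY:
            raise ValueError("event_day must lie in 1..90")


def derive_make90(record) -> Make90Outcome:
    """Derive the composite outcome for one patient record.

    ``record`` is any mapping with keys ``death_day``, ``pre_aki_egfr``,
    ``egfr_day90``, ``rrt_through_day28`` and ``rrt_at_day90``.
    """
    death_day = record["death_day"]
    egfr90 = record["egfr_day90"]
    components: set[str] = set()
    days: list[int] = []

    if death_day is not None and not pd.isna(death_day):
        components.add("death")
        days.append(int(death_day))
    if egfr90 is not None and not pd.isna(egfr90):
        pre = record["pre_aki_egfr"]
        if pre is None or pd.isna(pre) or pre <= 0:
            raise ValueError("pre_aki_egfr must be positive when egfr_day90 is present")
        if egfr90 < (1.0 - EGFR_DROP_FRACTION) * pre:  # strict >25% drop
            components.add("egfr_drop")
            days.append(HORIZON_DAY)
    if record["rrt_through_day28"]:
        components.add("rrt")
        days.append(RRT28_DAY)
    elif record["rrt_at_day90"]:
        components.add("rrt")
        days.append(HORIZON_DAY)

    if components:
        return Make90Outcome(True, min(days), frozenset(components))
    return Make90Outcome(False, HORIZON_DAY, frozenset())


def derive_make90_table(cohort: Cohort) -> pd.DataFrame:
    """Vectorized :func:`derive_make90` over a cohort.

    Returns a frame indexed like the cohort with columns ``event`` (bool),
    ``event_day`` (int) and one boolean column per component.
    """
    df = cohort.data
    death = df["death_day"].notna().to_numpy()
    death_day = df["death_day"].to_numpy(dtype=float)

    egfr90 = df["egfr_day90"].to_numpy(dtype=float)
    pre = df["pre_aki_egfr"].to_numpy(dtype=float)
    has_egfr = ~np.isnan(egfr90)
    if np.any(has_egfr & (np.isnan(pre) | (pre <= 0))):
        raise ValueError("pre_aki_egfr must be positive when egfr_day90 is present")
    egfr_drop = has_egfr & (egfr90 < (1.0 - EGFR_DROP_FRACTION) * pre)

    rrt28 = df["rrt_through_day28"].to_numpy(dtype=bool)
    rrt90 = df["rrt_at_day90"].to_numpy(dtype=bool)
    rrt = rrt28 | rrt90

    event = death | egfr_drop | rrt
    day = np.full(len(df), float(HORIZON_DAY))
    day = np.where(rrt28, np.minimum(day, RRT28_DAY), day)
    day = np.where(death, np.minimum(day, death_day), day)
    return pd.DataFrame(
        {
            "event": event,
            "event_day": day.astype(int),
            "death": death,
            "egfr_drop": egfr_drop,
            "rrt": rrt,
        },
        index=df.index,
    )


def cumulative_incidence(outcomes: pd.DataFrame, day: int) -> float:
    """1 − Kaplan–Meier survival at ``day`` for an ``event``/``event_day`` frame."""
    if len(outcomes) == 0:
        raise ValueError("empty outcome table")
    if not 1 <= day <= HORIZON_DAY:
        raise ValueError("day must lie in 1..90")
    km = KaplanMeierFitter()
    km.fit(outcomes["event_day"], event_observed=outcomes["event"])
    return float(1.0 - km.predict(day))


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    #: per distinct event time: (time, at-risk A, at-risk B, events A, events B)
    table: pd.DataFrame = field(repr=False, default=None)


def _logrank_statistic(t_a, e_a, t_b, e_b) -> float:
    times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    sa, sb = np.sort(t_a), np.sort(t_b)
    n1 = len(t_a) - np.searchsorted(sa, times, side="left")
    n2 = len(t_b) - np.searchsorted(sb, times, side="left")
    ea_sorted = np.sort(t_a[e_a])
    eb_sorted = np.sort(t_b[e_b])
    d1 = np.searchsorted(ea_sorted, times, side="right") - np.searchsorted(ea_sorted, times, side="left")
    d2 = np.searchsorted(eb_sorted, times, side="right") - np.searchsorted(eb_sorted, times, side="left")
    n = (n1 + n2).astype(float)
    d = (d1 + d2).astype(float)
    o_minus_e = float((d1 - d * n1 / n).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    var = float(np.where(n > 1, terms, 0.0).sum())
    return o_minus_e**2 / var if var > 0 else 0.0


def logrank_permutation_pvalue(outcomes_a: pd.DataFrame, outcomes_b: pd.DataFrame) -> float:
    """Exact p by enumerating every assignment of subjects to the two groups.

    Feasible only for small pooled sizes; intended as the exact companion to
    the asymptotic chi-square p of :func:`logrank_test`.
    """
    from itertools import combinations

    t = np.concatenate([outcomes_a["event_day"].to_numpy(dtype=float),
                        outcomes_b["event_day"].to_numpy(dtype=float)])
    e = np.concatenate([outcomes_a["event"].to_numpy(dtype=bool),
                        outcomes_b["event"].to_numpy(dtype=bool)])
    n, n_a = len(t), len(outcomes_a)
    observed = _logrank_statistic(t[:n_a], e[:n_a], t[n_a:], e[n_a:])
    count = total = 0
    for combo in combinations(range(n), n_a):
        in_a = np.zeros(n, dtype=bool)
        in_a[list(combo)] = True
        stat = _logrank_statistic(t[in_a], e[in_a], t[~in_a], e[~in_a])
        count += stat >= observed - 1e-12
        total += 1
    return count / total


def logrank_test(outcomes_a: pd.DataFrame, outcomes_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance at tied times."""
    if len(outcomes_a) == 0 or len(outcomes_b) == 0:
        raise ValueError("both groups must be non-empty")
    t_a = outcomes_a["event_day"].to_numpy(dtype=float)
    e_a = outcomes_a["event"].to_numpy(dtype=bool)
    t_b = outcomes_b["event_day"].to_numpy(dtype=float)
    e_b = outcomes_b["event"].to_numpy(dtype=bool)
    if not (e_a.any() or e_b.any()):
        raise ValueError("no events in either group")

    times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    sa, sb = np.sort(t_a), np.sort(t_b)
    n1 = len(t_a) - np.searchsorted(sa, times, side="left")
    n2 = len(t_b) - np.searchsorted(sb, times, side="left")
    ea_sorted = np.sort(t_a[e_a])
    eb_sorted = np.sort(t_b[e_b])
    d1 = np.searchsorted(ea_sorted, times, side="right") - np.searchsorted(ea_sorted, times, side="left")
    d2 = np.searchsorted(eb_sorted, times, side="right") - np.searchsorted(eb_sorted, times, side="left")

    n = (n1 + n2).astype(float)
    d = (d1 + d2).astype(float)
    o_minus_e = float((d1 - d * n1 / n).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    var = float(np.where(n > 1, terms, 0.0).sum())

    statistic = o_minus_e**2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(statistic, df=1)) if var > 0 else 1.0
    table = pd.DataFrame(
        {"time": times, "at_risk_a": n1, "at_risk_b": n2, "events_a": d1, "events_b": d2}
    )
    return LogRankResult(statistic=float(statistic), df=1, p_value=p, table=table)


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann–Whitney U p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def chi_square_2x2(table, correction: bool = False) -> float:
    """Two-sided chi-square p-value for a 2x2 count table (no Yates by default)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.pvalue)


@dataclass(frozen=True)
class RiskRatio:
    value: float
    defined: bool

    def __float__(self) -> float:
        return self.value if self.defined else float("nan")


def risk_ratio(events_e: int, n_e: int, events_u: int, n_u: int) -> RiskRatio:
    """Cumulative-incidence ratio exposed/unexposed; flagged undefined when CIu = 0."""
    if n_e <= 0 or n_u <= 0:
        raise ValueError("group sizes must be positive")
    if events_e < 0 or events_u < 0:
        raise ValueError("event counts must be non-negative")
    ci_e = events_e / n_e
    ci_u = events_u / n_u
    if ci_u == 0:
        return RiskRatio(float("nan"), defined=False)
    return RiskRatio(ci_e / ci_u, defined=True)


def smd_profile(matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Standardized mean difference of each variable per group vs the whole cohort.

    SMD = (group mean − cohort mean) / cohort SD (sample SD, ddof=1).
    Returns a frame indexed by group label with one column per variable.
    """
    labels = np.asarray(labels)
    if len(labels) != len(matrix):
        raise ValueError("labels must partition the rows of the matrix")
    cohort_mean = matrix.mean(axis=0)
    cohort_sd = matrix.std(axis=0, ddof=1)
    if (cohort_sd == 0).any():
        zero = list(matrix.columns[cohort_sd == 0])
        raise ValueError(f"zero cohort SD for variables {zero}")
    rows = {}
    for lab in np.unique(labels):
        group = matrix.loc[labels == lab]
        rows[lab] = (group.mean(axis=0) - cohort_mean) / cohort_sd
    return pd.DataFrame(rows).T
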