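"""Quartile risk-ratio screening and slope ranking of baseline variables.

For each candidate variable, patients are split into quartiles of the
baseline value; within each quartile the ratio of composite-event incidence
in the active arm to the placebo arm is computed.  Variables whose risk
ratios move monotonically across at least three consecutive quartiles pass
the screen; passing variables are ranked by the steepness of an ordinary
least-squares slope of risk ratio on quartile index, and the top-k are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .outcomes_stats import RiskRatio

N_QUARTILES = 4
MIN_RUN = 3


@dataclass(frozen=True)
class QuartileCell:
    n_e: int
    events_e: int
    n_u: int
    events_u: int

    @property
    def ci_e(self) -> float:
        return self.events_e / self.n_e if self.n_e else float("nan")

    @property
    def ci_u(self) -> float:
        return self.events_u / self.n_u if self.n_u else float("nan")

    @property
    def rr(self) -> RiskRatio:
        if self.n_e == 0 or self.n_u == 0 or self.ci_u == 0:
            return RiskRatio(float("nan"), defined=False)
        return RiskRatio(self.ci_e / self.ci_u, defined=True)


@dataclass(frozen=True)
class MonotoneRun:
    start_q: int
    end_q: int
    direction: str  # "increasing" | "decreasing"

    @property
    def length(self) -> int:
        return self.end_q - self.start_q + 1


@dataclass
class QuartileRiskProfile:
    variable: str
    boundaries: tuple[float, float, float]
    cells: tuple[QuartileCell, QuartileCell, QuartileCell, QuartileCell]
    monotone_runs: list[MonotoneRun] = field(default_factory=list)

    @property
    def rr_values(self) -> np.ndarray:
        return np.array([float(c.rr) for c in self.cells])

    @property
    def passed(self) -> bool:
        return any(r.length >= MIN_RUN for r in self.monotone_runs)


@dataclass(frozen=True)
class SlopeRecord:
    variable: str
    run: tuple[int, int]
    slope: float

    @property
    def steepness(self) -> float:
        return abs(self.slope)


def assign_quartiles(values) -> np.ndarray:
    """Quartile index 1..4 per value by rank; ties share the lowest rank's quartile.

    Missing values get NaN.  Requires at least 8 non-missing and 4 distinct
    values, otherwise the variable carries no quartile information.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    v = values[obs]
    if len(v) < 2 * N_QUARTILES:
        raise ValueError("need at least 8 non-missing values")
    if len(np.unique(v)) < N_QUARTILES:
        raise ValueError("non-informative variable: fewer than 4 distinct values")
    ranks = stats.rankdata(v, method="min")
    q = np.ceil(ranks * N_QUARTILES / len(v)).astype(float)
    out = np.full(values.shape, np.nan)
    out[obs] = q
    return out


def quartile_boundaries(values, quartiles) -> tuple[float, float, float]:
    """Largest observed value inside each of the first three quartiles."""
    values = np.asarray(values, dtype=float)
    cuts = []
    for q in (1, 2, 3):
        in_q = values[quartiles == q]
        cuts.append(float(in_q.max()) if len(in_q) else float("nan"))
    return tuple(cuts)


def quartile_risk_ratios(
    cohort: Cohort, outcomes: pd.DataFrame, variable: str
) -> QuartileRiskProfile:
    """Per-quartile incidences and active/placebo risk ratios for one variable.

    Quartiles are computed on the pooled cohort (both arms); patients missing
    the variable are excluded from its quartiles only.  Quartiles with an
    empty arm or zero placebo incidence get an undefined-flagged risk ratio.
    """
    arms = cohort.data["arm"].to_numpy()
    if not {"active", "placebo"} <= set(arms):
        raise ValueError("both arms must be represented in the cohort")
    values = cohort.data[variable].to_numpy(dtype=float)
    q = assign_quartiles(values)
    events = outcomes["event"].to_numpy(dtype=bool)

    cells = []
    for qi in range(1, N_QUARTILES + 1):
        in_q = q == qi
        e = in_q & (arms == "active")
        u = in_q & (arms == "placebo")
        cells.append(
            QuartileCell(
                n_e=int(e.sum()), events_e=int(events[e].sum()),
                n_u=int(u.sum()), events_u=int(events[u].sum()),
            )
        )
    profile = QuartileRiskProfile(
        variable=variable,
        boundaries=quartile_boundaries(values, q),
        cells=tuple(cells),
    )
    profile.monotone_runs = screen_monotone(profile).runs
    return profile


@dataclass
class MonotoneScreen:
    passed: bool
    runs: list[MonotoneRun]


def screen_monotone(profile: QuartileRiskProfile, strict: bool = True) -> MonotoneScreen:
    """Find maximal runs of ≥3 consecutive quartiles with monotone risk ratios.

    Undefined risk ratios break a run.  ``strict=False`` treats flat steps as
    run-compatible (non-strict monotonicity).
    """
    rr = profile.rr_values
    runs = _monotone_runs(rr, strict=strict)
    long_runs = [r for r in runs if r.length >= MIN_RUN]
    return MonotoneScreen(passed=bool(long_runs), runs=long_runs)


def _monotone_runs(rr: np.ndarray, strict: bool = True) -> list[MonotoneRun]:
    runs: list[MonotoneRun] = []
    n = len(rr)
    for direction, cmp in (("increasing", np.greater), ("decreasing", np.less)):
        if not strict:
            cmp = np.greater_equal if direction == "increasing" else np.less_equal
        start = 0
        while start < n:
            if np.isnan(rr[start]):
                start += 1
                continue
            end = start
            while (
                end + 1 < n
                and not np.isnan(rr[end + 1])
                and cmp(rr[end + 1], rr[end])
            ):
                end += 1
            if end > start:
                runs.append(MonotoneRun(start + 1, end + 1, direction))
            start = end + 1
    return runs


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def run_slopes(profile: QuartileRiskProfile) -> list[SlopeRecord]:
    """OLS slopes of risk ratio on quartile index over each monotone run.

    A full-length (four-quartile) run yields two slopes, one over quartiles
    1–3 and one over 2–4; length-3 runs yield a single slope.
    """
    rr = profile.rr_values
    records = []
    for run in profile.monotone_runs:
        if run.length >= N_QUARTILES:
            windows = [(1, 3), (2, 4)]
        else:
            windows = [(run.start_q, run.end_q)]
        for lo, hi in windows:
            qs = np.arange(lo, hi + 1)
            records.append(
                SlopeRecord(profile.variable, (lo, hi), _ols_slope(rr[qs - 1], qs.astype(float)))
            )
    return records


def slope_rank(profiles: list[QuartileRiskProfile], top_k: int = 15) -> pd.DataFrame:
    """Rank screened variables by maximum slope steepness; keep the top ``top_k``.

    Returns a frame with one row per (variable, run) slope, ordered by the
    owning variable's rank; only rows of retained variables are returned.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    passing = [p for p in profiles if p.passed]
    records = [rec for p in passing for rec in run_slopes(p)]
    if not records:
        raise ValueError("no variable passed the monotonicity screen")
    best = {}
    for rec in records:
        if rec.variable not in best or rec.steepness > best[rec.variable]:
            best[rec.variable] = rec.steepness
    order = sorted(best, key=lambda v: (-best[v], v))
    if len(order) < top_k:
        warnings.warn(
            f"only {len(order)} variables passed the screen; returning all of them"
        )
    kept = order[:top_k]
    rows = [
        {
            "variable": rec.variable,
            "run_start": rec.run[0],
            "run_end": rec.run[1],
            "slope": rec.slope,
            "steepness": rec.steepness,
            "rank": kept.index(rec.variable) + 1,
        }
        for rec in records
        if rec.variable in kept
    ]
    out = pd.DataFrame(rows).sort_values(["rank", "run_start"]).reset_index(drop=True)
    return out


def select_variables(
    cohort: Cohort, outcomes: pd.DataFrame, top_k: int = 15
) -> tuple[list[str], pd.DataFrame, list[QuartileRiskProfile]]:
    """Full screening pass over every baseline variable of the cohort.

    Variables with too few distinct values are skipped with a warning.
    Returns (ranked variable names, slope table, all computed profiles).
    """
    profiles = []
    for var in cohort.baseline_vars:
        try:
            profiles.append(quartile_risk_ratios(cohort, outcomes, var))
        except ValueError as exc:
            warnings.warn(f"skipping {var!r}: {exc}")
    table = slope_rank(profiles, top_k=top_k)
    ranked = list(dict.fromkeys(table["variable"]))
    return ranked, table, profiles
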