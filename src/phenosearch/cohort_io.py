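"""Reading, writing and validating patient-level trial tables.

A cohort is a plain :class:`pandas.DataFrame` with a fixed set of reserved
columns (identifiers, arm, exclusion flags and outcome fields) plus one
numeric column per baseline variable.  The :class:`Cohort` wrapper keeps the
frame together with the list of baseline-variable names so downstream stages
never have to guess which columns are clinical measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Columns every cohort table must carry, in canonical order.
RESERVED_COLUMNS = [
    "patient_id",
    "arm",
    "covid_confirmed",
    "prior_rrt",
    "pre_aki_egfr",
    "death_day",
    "rrt_through_day28",
    "rrt_at_day90",
    "egfr_day90",
]

ARMS = ("active", "placebo")

_BOOL_COLUMNS = ["covid_confirmed", "prior_rrt", "rrt_through_day28", "rrt_at_day90"]


class CohortFormatError(ValueError):
    """Raised when a cohort table violates its structural contract."""


@dataclass(frozen=True)
class Variable:
    """One entry of the variable dictionary."""

    name: str
    units: str = ""
    lower: float | None = None
    upper: float | None = None
    log_ok: bool = True


@dataclass
class VariableDictionary:
    """Named baseline variables with units, plausible ranges and log flags."""

    variables: dict[str, Variable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, var in self.variables.items():
            if name != var.name:
                raise CohortFormatError(f"dictionary key {name!r} != variable name {var.name!r}")
            if var.lower is not None and var.upper is not None and not var.lower < var.upper:
                raise CohortFormatError(f"variable {name!r}: range [{var.lower}, {var.upper}] is empty")

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    @classmethod
    def from_yaml(cls, path) -> "VariableDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        variables = {}
        for name, spec in raw.items():
            spec = spec or {}
            variables[name] = Variable(
                name=name,
                units=spec.get("units", ""),
                lower=spec.get("lower"),
                upper=spec.get("upper"),
                log_ok=spec.get("log_ok", True),
            )
        return cls(variables)

    def to_yaml(self, path) -> None:
        raw = {
            v.name: {"units": v.units, "lower": v.lower, "upper": v.upper, "log_ok": v.log_ok}
            for v in self.variables.values()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class Cohort:
    """A validated patient table plus the names of its baseline variables."""

    data: pd.DataFrame
    baseline_vars: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortFormatError(f"missing required columns: {missing}")
        ids = self.data["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise CohortFormatError(f"duplicate patient_id values: {dupes}")
        if self.data["arm"].isna().any():
            raise CohortFormatError("arm must be non-missing for every patient")
        bad_arms = set(self.data["arm"].unique()) - set(ARMS)
        if bad_arms:
            raise CohortFormatError(f"unknown arm values: {sorted(bad_arms)}")
        dd = self.data["death_day"].dropna()
        if len(dd) and not ((dd >= 1) & (dd <= 90)).all():
            raise CohortFormatError("death_day must lie in 1..90 when present")
        absent = [v for v in self.baseline_vars if v not in self.data.columns]
        if absent:
            raise CohortFormatError(f"baseline variables not in table: {absent}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), list(self.baseline_vars))


def _coerce_types(df: pd.DataFrame, baseline_vars: list[str]) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in _BOOL_COLUMNS:
        vals = df[col]
        if vals.dtype == object:
            mapped = vals.map({"True": True, "False": False, True: True, False: False})
            if mapped.isna().any():
                raise CohortFormatError(f"column {col!r} contains non-boolean values")
            df[col] = mapped.astype(bool)
        else:
            df[col] = vals.astype(bool)
    for col in ["pre_aki_egfr", "egfr_day90", "death_day", *baseline_vars]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CohortFormatError(f"column {col!r} contains unparseable numerics: {exc}") from exc
    return df


def read_cohort(path, dictionary: VariableDictionary | None = None) -> Cohort:
    """Read a cohort CSV (empty cell = missing) into a typed :class:`Cohort`.

    Values outside the dictionary's declared range are reported as warnings
    but kept; structural violations raise :class:`CohortFormatError`.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required columns {missing}")
    if dictionary is not None:
        baseline_vars = [v for v in dictionary.names if v in df.columns]
        unknown = [c for c in df.columns if c not in RESERVED_COLUMNS and c not in dictionary]
        if unknown:
            warnings.warn(f"columns not in the variable dictionary ignored as baseline vars: {unknown}")
    else:
        baseline_vars = [c for c in df.columns if c not in RESERVED_COLUMNS]
    df = _coerce_types(df, baseline_vars)
    if dictionary is not None:
        for name in baseline_vars:
            var = dictionary.variables[name]
            vals = df[name].dropna()
            out = pd.Series(False, index=vals.index)
            if var.lower is not None:
                out |= vals < var.lower
            if var.upper is not None:
                out |= vals > var.upper
            if out.any():
                warnings.warn(
                    f"variable {name!r}: {int(out.sum())} value(s) outside "
                    f"declared range [{var.lower}, {var.upper}]"
                )
    return Cohort(df, baseline_vars)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; missing cells become empty strings."""
    cols = RESERVED_COLUMNS + cohort.baseline_vars
    df = cohort.data[cols].copy()
    # Int-valued death days render without a trailing ".0" so files stay tidy.
    df["death_day"] = df["death_day"].astype("Int64") if _all_integral(df["death_day"]) else df["death_day"]
    df.to_csv(path, index=False)


def _all_integral(series: pd.Series) -> bool:
    vals = series.dropna()
    return bool(len(vals) == 0 or (vals == vals.round()).all())


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Drop pre-specified exclusions and log counts per reason.

    Patients flagged for both reasons are attributed to ``covid`` in the log
    (first-listed reason wins); the surviving rows are untouched.
    """
    df = cohort.data
    covid = df["covid_confirmed"].to_numpy(dtype=bool)
    prior = df["prior_rrt"].to_numpy(dtype=bool)
    log = {"covid": int(covid.sum()), "prior_rrt": int((prior & ~covid).sum())}
    kept = df.loc[~(covid | prior)].reset_index(drop=True)
    return Cohort(kept, list(cohort.baseline_vars)), log
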