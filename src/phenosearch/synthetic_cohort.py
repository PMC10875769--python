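"""Synthetic trial cohorts with a planted two-phenotype structure.

The real trial data are proprietary, so every downstream stage is exercised
on cohorts generated here: each patient gets a latent phenotype, an arm, a
set of Gaussian baseline variables whose means differ by phenotype, and a
composite kidney outcome whose probability depends on (phenotype, arm).  The
generator returns the ground-truth labels alongside the cohort so recovery
can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort_io import RESERVED_COLUMNS, Cohort

__all__ = [
    "VariableSpec",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_cohort",
    "inject_missingness",
    "inject_outliers",
    "default_variable_specs",
]


@dataclass(frozen=True)
class VariableSpec:
    """Per-phenotype Gaussian parameters for one baseline variable."""

    name: str
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ValueError(f"{self.name}: means and sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"{self.name}: SDs must be positive")


def default_variable_specs(n_phenotypes: int = 2, n_fillers: int = 0) -> list[VariableSpec]:
    """Eight named clinical variables plus optional uninformative fillers.

    Phenotype means are desk-scale values in clinically plausible units
    (severity scores higher and bicarbonate/eGFR lower in phenotype 2).
    """
    named = [
        VariableSpec("apache_ii", (20.0, 26.5), (5.0, 5.5)),
        VariableSpec("msofa", (8.0, 9.5), (2.0, 2.2)),
        VariableSpec("bicarbonate", (22.0, 17.5), (3.0, 2.8)),
        VariableSpec("hematocrit", (32.8, 35.1), (6.0, 6.5)),
        VariableSpec("lactate", (1.7, 4.0), (0.9, 2.0)),
        VariableSpec("egfr", (60.0, 35.0), (20.0, 15.0)),
        VariableSpec("pao2_fio2", (250.0, 180.0), (80.0, 70.0)),
        VariableSpec("creatinine", (1.6, 2.6), (0.6, 0.9)),
    ]
    if n_phenotypes != 2:
        named = [
            VariableSpec(v.name, tuple(v.means[i % 2] for i in range(n_phenotypes)),
                         tuple(v.sds[i % 2] for i in range(n_phenotypes)))
            for v in named
        ]
    fillers = [
        VariableSpec(f"filler_{i:02d}", (50.0,) * n_phenotypes, (10.0,) * n_phenotypes)
        for i in range(1, n_fillers + 1)
    ]
    return named + fillers


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults give a two-phenotype trial."""

    n_patients: int = 570
    phenotype_weights: tuple[float, ...] = (0.58, 0.42)
    arm_ratio: float = 0.5
    variable_specs: list[VariableSpec] = field(default_factory=default_variable_specs)
    #: (phenotype, arm) -> 90-day composite event probability
    event_risk: dict[tuple[int, str], float] = field(
        default_factory=lambda: {
            (1, "placebo"): 0.458,
            (1, "active"): 0.494,
            (2, "placebo"): 0.678,
            (2, "active"): 0.541,
        }
    )
    #: probabilities dividing events among death / rrt / egfr_drop
    component_split: tuple[float, float, float] = (0.45, 0.35, 0.20)
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0
    excluded_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if len(self.phenotype_weights) < 2:
            raise ValueError("need at least two phenotypes")
        if abs(sum(self.phenotype_weights) - 1.0) > 1e-9:
            raise ValueError("phenotype_weights must sum to 1")
        if not self.variable_specs:
            raise ValueError("variable_specs must be non-empty")
        probs = [self.arm_ratio, self.missing_rate, self.outlier_rate, self.excluded_rate,
                 *self.phenotype_weights, *self.component_split, *self.event_risk.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not (1.0 - 1e-9) <= sum(self.component_split) <= (1.0 + 1e-9):
            raise ValueError("component_split must sum to 1")
        if self.missing_rate >= 1.0 or self.outlier_rate >= 1.0:
            raise ValueError("rates must be < 1")
        n_ph = len(self.phenotype_weights)
        for spec in self.variable_specs:
            if len(spec.means) != n_ph:
                raise ValueError(f"{spec.name}: needs one mean/SD per phenotype")
        for ph in range(1, n_ph + 1):
            for arm in ("active", "placebo"):
                if (ph, arm) not in self.event_risk:
                    raise ValueError(f"event_risk missing ({ph}, {arm})")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "variable_specs" in raw:
            raw["variable_specs"] = [
                VariableSpec(v["name"], tuple(v["means"]), tuple(v["sds"]))
                for v in raw["variable_specs"]
            ]
        if "event_risk" in raw:
            raw["event_risk"] = {
                (int(k.split(":")[0]), k.split(":")[1]): float(v)
                for k, v in raw["event_risk"].items()
            }
        for key in ("phenotype_weights", "component_split"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Latent labels and planted probabilities for one simulated cohort."""

    labels: pd.Series  # patient_id -> phenotype (1-based)
    event_risk: dict[tuple[int, str], float]
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.labels.index, "phenotype": self.labels.values})


def simulate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort table and its ground truth from ``config``.

    Event days for death/RRT components are uniform on 1..90; events carried
    only by the eGFR-drop component are assessed (and thus timed) at day 90.
    Identical configs produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_ph = len(config.phenotype_weights)

    phenotype = rng.choice(np.arange(1, n_ph + 1), size=n, p=config.phenotype_weights)
    arm = np.where(rng.random(n) < config.arm_ratio, "active", "placebo")

    baseline = {}
    for spec in config.variable_specs:
        means = np.array(spec.means)[phenotype - 1]
        sds = np.array(spec.sds)[phenotype - 1]
        baseline[spec.name] = rng.normal(means, sds)

    risk = np.array([config.event_risk[(ph, a)] for ph, a in zip(phenotype, arm)])
    event = rng.random(n) < risk
    component = rng.choice(3, size=n, p=np.asarray(config.component_split) / sum(config.component_split))
    event_day = rng.integers(1, 91, size=n)

    pre_aki_egfr = rng.normal(75.0, 12.0, size=n).clip(min=20.0)
    death_day = np.full(n, np.nan)
    rrt28 = np.zeros(n, dtype=bool)
    rrt90 = np.zeros(n, dtype=bool)
    egfr_day90 = np.full(n, np.nan)

    is_death = event & (component == 0)
    is_rrt = event & (component == 1)
    is_egfr = event & (component == 2)
    death_day[is_death] = event_day[is_death]
    rrt28[is_rrt] = event_day[is_rrt] <= 28
    rrt90[is_rrt & ~rrt28] = True
    # survivors get a day-90 eGFR; drop >25% only for planted eGFR events
    alive = ~is_death
    egfr_day90[alive] = 0.90 * pre_aki_egfr[alive] * np.exp(rng.normal(0.0, 0.05, size=int(alive.sum())))
    egfr_day90[alive] = np.maximum(egfr_day90[alive], 0.751 * pre_aki_egfr[alive])
    egfr_day90[is_egfr] = 0.60 * pre_aki_egfr[is_egfr]

    excluded = rng.random(n) < config.excluded_rate
    covid = excluded & (rng.random(n) < 0.5)
    prior_rrt = excluded & ~covid

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "arm": arm,
            "covid_confirmed": covid,
            "prior_rrt": prior_rrt,
            "pre_aki_egfr": pre_aki_egfr,
            "death_day": death_day,
            "rrt_through_day28": rrt28,
            "rrt_at_day90": rrt90,
            "egfr_day90": egfr_day90,
            **baseline,
        }
    )
    cohort = Cohort(df, [s.name for s in config.variable_specs])

    if config.outlier_rate > 0:
        cohort, _ = inject_outliers(
            cohort, config.outlier_rate, config.outlier_magnitude,
            seed=int(rng.integers(2**31)),
        )
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, seed=int(rng.integers(2**31)))

    truth = GroundTruth(
        labels=pd.Series(phenotype, index=df["patient_id"].to_numpy(), name="phenotype"),
        event_risk=dict(config.event_risk),
        seed=config.seed,
    )
    return cohort, truth


def inject_missingness(cohort: Cohort, rate: float, seed: int) -> Cohort:
    """Set baseline cells missing completely at random at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    block = out.data[out.baseline_vars].to_numpy(dtype=float)
    mask = rng.random(block.shape) < rate
    block[mask] = np.nan
    out.data[out.baseline_vars] = block
    return out


def inject_outliers(
    cohort: Cohort, rate: float, magnitude: float, seed: int
) -> tuple[Cohort, list[str]]:
    """Shift one baseline variable of selected patients by ±magnitude·SD.

    ``magnitude`` must be ≥ 3 so injected points are unambiguous outliers.
    Returns the modified cohort and the ids of the shifted patients.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if magnitude < 3:
        raise ValueError("magnitude must be at least 3 SDs")
    out = cohort.copy()
    if rate == 0.0:
        return out, []
    rng = np.random.default_rng(seed)
    hit = np.flatnonzero(rng.random(len(out.data)) < rate)
    sds = out.data[out.baseline_vars].std(ddof=1)
    ids = []
    for i in hit:
        var = out.baseline_vars[int(rng.integers(len(out.baseline_vars)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        cur = out.data.at[out.data.index[i], var]
        base = 0.0 if pd.isna(cur) else cur
        out.data.at[out.data.index[i], var] = base + sign * magnitude * sds[var]
        ids.append(str(out.data.at[out.data.index[i], "patient_id"]))
    return out, ids


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.frame().to_csv(path, index=False)
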