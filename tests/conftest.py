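import numpy as np
import pandas as pd
import pytest

from phenosearch.cohort_io import Cohort
from phenosearch.synthetic_cohort import SyntheticConfig, VariableSpec, simulate_cohort


def make_cohort_frame(rows: list[dict], baseline_vars: list[str]) -> Cohort:
    """Build a Cohort from partial row dicts, filling structural defaults."""
    defaults = {
        "arm": "active",
        "covid_confirmed": False,
        "prior_rrt": False,
        "pre_aki_egfr": 80.0,
        "death_day": np.nan,
        "rrt_through_day28": False,
        "rrt_at_day90": False,
        "egfr_day90": np.nan,
    }
    filled = []
    for i, row in enumerate(rows):
        merged = {"patient_id": f"P{i + 1:03d}", **defaults, **row}
        filled.append(merged)
    return Cohort(pd.DataFrame(filled), baseline_vars)


@pytest.fixture
def toy16_cohort():
    """16 patients, one variable with values 1..16, outcomes set by hand.

    Quartiles are exactly four groups of four; each quartile holds 2 active
    and 2 placebo patients.  Events per quartile (active, placebo):
    Q1 (2, 1), Q2 (1, 1), Q3 (1, 2), Q4 (0, 2), giving risk ratios
    2.0, 1.0, 0.5, 0.0 — strictly decreasing across all four quartiles.
    """
    events_active = {1: 2, 2: 1, 3: 1, 4: 0}
    events_placebo = {1: 1, 2: 1, 3: 2, 4: 2}
    rows = []
    for q in range(1, 5):
        for arm, n_events in (("active", events_active[q]), ("placebo", events_placebo[q])):
            for j in range(2):
                rows.append(
                    {
                        "arm": arm,
                        "marker": len(rows) + 1,  # values 1..16 in construction order
                        "death_day": 10.0 if j < n_events else np.nan,
                    }
                )
    return make_cohort_frame(rows, ["marker"])


@pytest.fixture
def small_synthetic():
    cfg = SyntheticConfig(n_patients=200, seed=7)
    return simulate_cohort(cfg)


def informative_config(seed: int, sep: float = 2.0, n: int = 570,
                       n_informative: int = 4, n_noise: int = 2) -> SyntheticConfig:
    """Cohort config with planted separable phenotypes (criterion-5 setup)."""
    specs = [
        VariableSpec(f"inf_{i}", (0.0, sep), (1.0, 1.0)) for i in range(n_informative)
    ] + [
        VariableSpec(f"noise_{i}", (0.0, 0.0), (1.0, 1.0)) for i in range(n_noise)
    ]
    return SyntheticConfig(n_patients=n, variable_specs=specs, seed=seed)


def null_config(seed: int, n: int = 200) -> SyntheticConfig:
    """No phenotype structure and no treatment effect anywhere."""
    specs = [VariableSpec(f"v{i}", (0.0, 0.0), (1.0, 1.0)) for i in range(4)]
    risk = {(ph, arm): 0.5 for ph in (1, 2) for arm in ("active", "placebo")}
    return SyntheticConfig(
        n_patients=n, variable_specs=specs, event_risk=risk, seed=seed
    )
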