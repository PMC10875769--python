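"""Phenotype characterization tables, incidence curves and the pipeline driver."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import outcomes_stats as osx
from .cohort_io import Cohort, apply_exclusions, read_cohort, write_cohort
from .model_search import ClusteringParams, ModelEvaluation, search_models, select_best
from .preprocessing import PrepConfig
from .synthetic_cohort import SyntheticConfig, simulate_cohort, write_ground_truth
from .variable_selection import select_variables


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so 54.05 -> 54.1, not banker's 54.0)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage of ``count`` over ``denom``, rounded half away from zero."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * count / denom, decimals)


def format_count_percent(count: int, denom: int, decimals: int = 1) -> str:
    """Render a categorical cell as ``count (pct%)``, e.g. ``66 (54.1%)``."""
    return f"{count} ({percent(count, denom, decimals):.{decimals}f}%)"


def median_iqr(values, decimals: int = 2) -> str:
    """Render a numeric cell as ``median [q1, q3]`` with linear-interpolation quantiles."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return ""
    med, q1, q3 = (np.percentile(vals, p) for p in (50, 25, 75))
    return f"{med:.{decimals}f} [{q1:.{decimals}f}, {q3:.{decimals}f}]"


@dataclass
class PhenotypeReport:
    """Characterization of the final phenotypes, one column per phenotype × arm."""

    group_sizes: dict[tuple[int, str], int]
    table: pd.DataFrame  # row per variable/outcome, column per (phenotype, arm)
    p_values: pd.Series  # between-phenotype tests per row
    smd: pd.DataFrame
    incidence_curves: dict[tuple[int, str], pd.DataFrame]


def characterize(cohort: Cohort, labels) -> PhenotypeReport:
    """Build a characterization table for given phenotype labels.

    Numeric rows show median [IQR] and a between-phenotype Mann–Whitney p;
    outcome rows show count (%) and a chi-square p.  Curves are Kaplan–Meier
    cumulative incidences per phenotype × arm.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort.data):
        raise ValueError("labels must cover the cohort")
    df = cohort.data
    outcomes = osx.derive_make90_table(cohort)
    phenos = sorted(np.unique(labels))
    if len(phenos) < 2:
        raise ValueError("need at least two phenotypes to characterize")
    arms = ("active", "placebo")

    groups = {
        (ph, arm): (labels == ph) & (df["arm"] == arm).to_numpy()
        for ph in phenos
        for arm in arms
    }
    group_sizes = {key: int(mask.sum()) for key, mask in groups.items()}
    for key, n in group_sizes.items():
        if n == 0:
            raise ValueError(f"empty phenotype/arm group {key}")

    death28 = (df["death_day"].notna() & (df["death_day"] <= 28)).to_numpy()
    death90 = df["death_day"].notna().to_numpy()
    binary_rows = {
        "make90": outcomes["event"].to_numpy(),
        "egfr_drop_day90": outcomes["egfr_drop"].to_numpy(),
        "rrt": outcomes["rrt"].to_numpy(),
        "mortality_day28": death28,
        "mortality_day90": death90,
    }

    cells: dict[str, dict] = {}
    pvals: dict[str, float] = {}
    ph_masks = {ph: labels == ph for ph in phenos}

    for var in cohort.baseline_vars + ["pre_aki_egfr"]:
        vals = df[var].to_numpy(dtype=float)
        cells[var] = {key: median_iqr(vals[mask]) for key, mask in groups.items()}
        a, b = vals[ph_masks[phenos[0]]], vals[ph_masks[phenos[1]]]
        try:
            pvals[var] = osx.mann_whitney_u(a, b)
        except ValueError:
            pvals[var] = float("nan")

    for name, flags in binary_rows.items():
        cells[name] = {
            key: format_count_percent(int(flags[mask].sum()), int(mask.sum()))
            for key, mask in groups.items()
        }
        tab = [
            [int(flags[ph_masks[ph]].sum()), int((~flags[ph_masks[ph]]).sum())]
            for ph in phenos[:2]
        ]
        try:
            pvals[name] = osx.chi_square_2x2(tab)
        except ValueError:
            pvals[name] = float("nan")

    table = pd.DataFrame(cells).T
    table.columns = [f"phenotype{ph}_{arm}" for (ph, arm) in groups]

    matrix = df[cohort.baseline_vars]
    keep = [c for c in matrix.columns if matrix[c].std(ddof=1) > 0]
    smd = osx.smd_profile(matrix[keep].fillna(matrix[keep].mean()), labels)

    curves = {}
    for (ph, arm), mask in groups.items():
        o = outcomes.loc[mask]
        km = KaplanMeierFitter()
        km.fit(o["event_day"], event_observed=o["event"])
        sf = km.survival_function_
        curves[(ph, arm)] = pd.DataFrame(
            {"day": sf.index.to_numpy(), "cumulative_incidence": 1.0 - sf.iloc[:, 0].to_numpy()}
        )

    return PhenotypeReport(
        group_sizes=group_sizes,
        table=table,
        p_values=pd.Series(pvals),
        smd=smd,
        incidence_curves=curves,
    )


class StageError(RuntimeError):
    """A pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs: a cohort source plus stage settings."""

    cohort_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    top_k: int = 15
    size_range: tuple[int, int] = (2, 4)
    algorithms: tuple[str, ...] = ("kmeans", "pam")
    search_reps: int = 100
    final_reps: int = 1000
    p_item: float = 0.8
    n_init: int = 3
    prep: PrepConfig = field(default_factory=PrepConfig)
    search_pool: int = 6  # cap on variables entering enumeration


def run_pipeline(config: PipelineConfig, seed: int, outdir) -> dict:
    """Execute exclusions → variable selection → model search → characterization.

    Writes all artifacts under ``outdir`` and returns the machine-readable
    summary (also written as ``summary.json``).  Deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "stages": {}}

    try:
        if config.synthetic is not None:
            syn = config.synthetic
            syn.seed = seed
            cohort, truth = simulate_cohort(syn)
            write_cohort(cohort, outdir / "cohort.csv")
            write_ground_truth(truth, outdir / "ground_truth.csv")
        elif config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            raise ValueError("config must provide cohort_csv or synthetic settings")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc
    n_input = len(cohort)

    try:
        cohort, exclusion_log = apply_exclusions(cohort)
    except Exception as exc:
        raise StageError("exclusions", exc) from exc
    summary["stages"]["exclusions"] = {**exclusion_log, "remaining": len(cohort)}

    try:
        outcomes = osx.derive_make90_table(cohort)
    except Exception as exc:
        raise StageError("outcomes", exc) from exc

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked, slope_table, _ = select_variables(cohort, outcomes, top_k=config.top_k)
        slope_table.to_csv(outdir / "selected_variables.csv", index=False)
    except Exception as exc:
        raise StageError("variable_selection", exc) from exc
    summary["stages"]["variable_selection"] = {"ranked": ranked}

    pool = ranked[: config.search_pool]
    hi = min(config.size_range[1], len(pool))
    lo = min(config.size_range[0], hi)
    try:
        params = ClusteringParams(reps=config.search_reps, p_item=config.p_item, n_init=config.n_init)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evaluations = search_models(
                cohort, pool, size_range=(lo, hi), algorithms=config.algorithms,
                params=params, seed=seed, prep_config=config.prep,
            )
        from .model_search import evaluations_table

        evaluations_table(evaluations).to_csv(outdir / "model_search.csv", index=False)
        best = select_best(evaluations)
    except Exception as exc:
        raise StageError("model_search", exc) from exc

    # re-run the winning model at full reps for the final labels
    try:
        from .model_search import evaluate_model

        final_params = ClusteringParams(reps=config.final_reps, p_item=config.p_item, n_init=config.n_init)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final = evaluate_model(cohort, best.spec, params=final_params, seed=seed,
                                   prep_config=config.prep)
        pd.DataFrame({"patient_id": final.ids, "phenotype": final.labels}).to_csv(
            outdir / "phenotypes.csv", index=False
        )
    except Exception as exc:
        raise StageError("final_model", exc) from exc

    try:
        analyzed = cohort.data[cohort.data["patient_id"].isin(final.ids)].reset_index(drop=True)
        analyzed_cohort = Cohort(analyzed, list(cohort.baseline_vars))
        labels = pd.Series(final.labels, index=final.ids).loc[analyzed["patient_id"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = characterize(analyzed_cohort, labels)
        report.table.to_csv(outdir / "characterization.csv")
        report.p_values.to_csv(outdir / "characterization_pvalues.csv", header=["p_value"])
        report.smd.to_csv(outdir / "smd.csv")
    except Exception as exc:
        raise StageError("characterization", exc) from exc

    b = final.benefiting or best.benefiting
    summary["stages"]["model_search"] = {
        "n_candidates": len(evaluations),
        "n_passing": int(sum(e.gate_consensus and e.gate_efficacy for e in evaluations)),
        "selected": {
            "variables": list(best.spec.variables),
            "algorithm": best.spec.algorithm,
            "k": best.spec.k,
        },
    }
    summary["stages"]["final_model"] = {
        "n_used": final.n_used,
        "cluster_consensus": {str(k): v for k, v in final.cluster_consensus.items()},
        "benefiting_phenotype": b.phenotype if b else None,
        "benefit_p": b.p_value if b else None,
    }
    summary["totals"] = {
        "input_rows": n_input,
        "excluded": n_input - summary["stages"]["exclusions"]["remaining"],
        "removed_preprocessing": summary["stages"]["exclusions"]["remaining"] - final.n_used,
        "analyzed": final.n_used,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def plot_incidence_curves(report: PhenotypeReport, path) -> None:
    """Optional cumulative-incidence plot per phenotype × arm."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (ph, arm), curve in report.incidence_curves.items():
        ax.step(curve["day"], curve["cumulative_incidence"], where="post",
                label=f"phenotype {ph}, {arm}")
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative incidence")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
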