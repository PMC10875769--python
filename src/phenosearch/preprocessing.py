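"""Per-model preprocessing: missingness filter, chained random-forest
imputation, log/scale/center transform and Bonferroni outlier removal.

The stage order is fixed: patients with too much missing data are dropped
first, remaining gaps are imputed, the matrix is transformed, and finally
outliers are removed (with a re-standardisation so the delivered matrix is
exactly centered and scaled)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .cohort_io import Cohort


@dataclass
class PreparedMatrix:
    """Imputed, transformed, outlier-free matrix for one candidate model."""

    ids: list[str]
    variables: list[str]
    X: pd.DataFrame
    removed: pd.DataFrame  # columns: patient_id, reason

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("prepared matrix must have no missing cells")
        if set(self.removed["patient_id"]) & set(self.ids):
            raise ValueError("removed ids overlap retained ids")


def filter_missingness(
    cohort: Cohort, model_vars: list[str], threshold: float = 0.5
) -> tuple[Cohort, list[str]]:
    """Drop patients with strictly more than ``threshold`` missing model cells."""
    if not model_vars:
        raise ValueError("model_vars must be non-empty")
    frac = cohort.data[model_vars].isna().mean(axis=1)
    drop = frac > threshold
    removed = cohort.data.loc[drop, "patient_id"].tolist()
    kept = Cohort(cohort.data.loc[~drop].reset_index(drop=True), list(cohort.baseline_vars))
    return kept, removed


def impute_chained_forest(
    matrix: pd.DataFrame,
    seed: int,
    max_iter: int = 10,
    n_trees: int = 100,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Fill missing cells by iterated per-column random-forest regression.

    Columns are visited in order of increasing missingness; each missing
    column is regressed on all the others and its gaps replaced with forest
    predictions.  Iteration stops when the average out-of-bag error stops
    improving (by ``tol``) or after ``max_iter`` sweeps.  Observed cells are
    never altered.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns to impute")
    na = matrix.isna()
    fully_missing = list(matrix.columns[na.all()])
    if fully_missing:
        raise ValueError(f"fully missing column(s): {fully_missing}")
    if not na.any().any():
        return matrix.copy()

    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float).copy()
    mask = na.to_numpy()
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[mask[:, j], j] = col_means[j]

    order = np.argsort(na.sum(axis=0).to_numpy())
    order = [j for j in order if mask[:, j].any()]

    prev_oob = np.inf
    for _ in range(max_iter):
        oob_errors = []
        for j in order:
            obs = ~mask[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(X[obs][:, others], X[obs, j])
            X[mask[:, j], j] = forest.predict(X[mask[:, j]][:, others])
            var_j = X[obs, j].var()
            oob_errors.append(1.0 - forest.oob_score_ if var_j > 0 else 0.0)
        oob = float(np.mean(oob_errors))
        if prev_oob - oob < tol:
            break
        prev_oob = oob

    out = matrix.copy()
    out.loc[:, :] = X
    # observed cells restored bit-exactly in case of float round trips
    out = out.where(na, matrix)
    return out


def transform_log_scale_center(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per column: (shifted) log, then center to mean 0 and scale to SD 1.

    Strictly positive columns get a plain log; columns containing values ≤ 0
    get ``log(x - min + 1)`` so the transform stays finite.
    """
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if len(obs) == 0 or obs.min() == obs.max():
            raise ValueError(f"degenerate variable {col!r}: constant or empty column")
        if obs.min() > 0:
            y = np.log(x)
        else:
            y = np.log(x - obs.min() + 1.0)
        sd = np.nanstd(y, ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"degenerate variable {col!r}: zero variance after log")
        out[col] = (y - np.nanmean(y)) / sd
    return pd.DataFrame(out, index=matrix.index)


def _studentized_bonferroni_p(y: np.ndarray, X_others: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted two-sided p per row for externally studentized residuals.

    Uses the closed form t_i = e_i * sqrt((n-p-1) / (SSE*(1-h_i) - e_i^2))
    instead of n leave-one-out refits.
    """
    from scipy import stats as sps

    n = len(y)
    exog = np.column_stack([np.ones(n), X_others])
    q, _ = np.linalg.qr(exog)
    hat = (q**2).sum(axis=1)
    coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ coef
    sse = float(resid @ resid)
    p_params = exog.shape[1]
    df = n - p_params - 1
    if df <= 0:
        raise ValueError("too few rows for studentized residuals")
    denom = sse * (1.0 - hat) - resid**2
    denom = np.maximum(denom, 1e-300)
    t = resid * np.sqrt(df / denom)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return np.minimum(p * n, 1.0)


def bonferroni_outlier_removal(
    matrix: pd.DataFrame, alpha: float = 0.05, max_rounds: int = 1
) -> tuple[pd.DataFrame, list]:
    """Remove rows flagged by a Bonferroni outlier test on each variable.

    Each variable is regressed on the remaining model variables; rows whose
    externally studentized residual has Bonferroni-adjusted p < ``alpha``
    (adjusted by the number of rows) are removed.  Repeats up to
    ``max_rounds`` times or until no row is flagged.
    """
    current = matrix.copy()
    removed: list = []
    for _ in range(max_rounds):
        n, p = current.shape
        if n < p + 2:
            raise ValueError("too few rows for the outlier test")
        X = current.to_numpy(dtype=float)
        flagged = np.zeros(n, dtype=bool)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            padj = _studentized_bonferroni_p(X[:, j], X[:, others])
            flagged |= padj < alpha
        if not flagged.any():
            break
        removed.extend(current.index[flagged].tolist())
        current = current.loc[~flagged]
    return current, removed


@dataclass
class PrepConfig:
    missing_threshold: float = 0.5
    impute_max_iter: int = 10
    impute_trees: int = 100
    outlier_alpha: float = 0.05
    outlier_rounds: int = 1
    skip_outlier_removal: bool = False


def prepare_matrix(
    cohort: Cohort,
    model_vars: list[str],
    seed: int,
    config: PrepConfig | None = None,
) -> PreparedMatrix:
    """Run the full fixed-order preprocessing pipeline for one model.

    After outlier removal the matrix is re-centered/re-scaled so the
    delivered columns have mean 0 and SD 1 exactly.
    """
    config = config or PrepConfig()
    kept, dropped_missing = filter_missingness(cohort, model_vars, config.missing_threshold)
    sub = kept.data.set_index("patient_id")[model_vars]
    if sub.isna().any().any():
        if sub.shape[1] >= 2:
            sub = impute_chained_forest(
                sub, seed=seed, max_iter=config.impute_max_iter, n_trees=config.impute_trees
            )
        else:
            sub = sub.fillna(sub.mean())
    transformed = transform_log_scale_center(sub)
    if config.skip_outlier_removal:
        final, outlier_ids = transformed, []
    else:
        final, outlier_ids = bonferroni_outlier_removal(
            transformed, alpha=config.outlier_alpha, max_rounds=config.outlier_rounds
        )
        if outlier_ids:
            final = (final - final.mean()) / final.std(ddof=1)
    removed = pd.DataFrame(
        {
            "patient_id": [*dropped_missing, *outlier_ids],
            "reason": ["missingness"] * len(dropped_missing) + ["outlier"] * len(outlier_ids),
        }
    )
    return PreparedMatrix(
        ids=list(final.index), variables=list(model_vars), X=final, removed=removed
    )
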