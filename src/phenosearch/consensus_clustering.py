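"""Consensus clustering built on in-package k-means and PAM.

Repeated clustering of row subsamples yields a consensus matrix whose entry
(i, j) is the fraction of co-samplings in which patients i and j landed in
the same cluster.  Final labels come from average-linkage hierarchical
clustering of 1 − consensus; per-cluster consensus scores and CDF areas
support the stability gate and the choice of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform


@dataclass(frozen=True)
class ModelSpec:
    """One candidate clustering model: a variable subset, algorithm and k."""

    variables: tuple[str, ...]
    algorithm: str = "kmeans"
    k: int = 2

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("variables must be non-empty")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variables must be unique")
        if self.algorithm not in ("kmeans", "pam"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.k < 2:
            raise ValueError("k must be at least 2")


def kmeans_fit(
    X: np.ndarray, k: int, seed: int, n_init: int = 10, max_iter: int = 100
) -> np.ndarray:
    """Lloyd's algorithm with random restarts; returns labels of the best restart."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError("k exceeds the number of rows")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d2 = cdist(X, centers, metric="sqeuclidean")
            new_labels = d2.argmin(axis=1)
            for c in range(k):
                members = X[new_labels == c]
                if len(members):
                    centers[c] = members.mean(axis=0)
                else:  # re-seed empty cluster at the worst-fit point
                    centers[c] = X[d2.min(axis=1).argmax()]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        inertia = float(((X - centers[labels]) ** 2).sum())
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels.copy()
    return best_labels


def _pam_swap(dist: np.ndarray, medoids: np.ndarray, max_iter: int) -> tuple[np.ndarray, float]:
    """Best-improvement SWAP phase; never increases the total dissimilarity."""
    n, k = len(dist), len(medoids)
    medoids = medoids.copy()
    cost = float(dist[:, medoids].min(axis=1).sum())
    for _ in range(max_iter):
        best_delta, best_swap = 1e-12, None
        d_med = dist[:, medoids]  # n x k
        for i in range(k):
            others = np.delete(np.arange(k), i)
            dmin_others = d_med[:, others].min(axis=1) if k > 1 else np.full(n, np.inf)
            # cost of every candidate replacement for medoid i at once
            cand_cost = np.minimum(dmin_others[:, None], dist).sum(axis=0)
            cand_cost[medoids] = np.inf
            j = int(cand_cost.argmin())
            delta = cost - float(cand_cost[j])
            if delta > best_delta:
                best_delta, best_swap = delta, (i, j)
        if best_swap is None:
            break
        i, j = best_swap
        medoids[i] = j
        cost -= best_delta
    return medoids, cost


def pam_fit(
    X: np.ndarray | None,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    dist: np.ndarray | None = None,
    n_restarts: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    Accepts either a data matrix (Euclidean dissimilarity) or a precomputed
    square distance matrix.  ``n_restarts`` extra SWAP runs from random
    medoid sets guard against swap-neighborhood local optima; the best
    solution overall is returned.
    """
    if dist is None:
        X = np.asarray(X, dtype=float)
        dist = cdist(X, X)
    n = len(dist)
    if k > n:
        raise ValueError("k exceeds the number of rows")

    # BUILD: start from the most central point, then greedily add the point
    # that most reduces total dissimilarity.
    medoids = [int(dist.sum(axis=0).argmin())]
    dmin = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(gains.argmax())
        medoids.append(nxt)
        dmin = np.minimum(dmin, dist[:, nxt])

    best_medoids, best_cost = _pam_swap(dist, np.array(medoids, dtype=int), max_iter)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = rng.choice(n, size=k, replace=False)
        cand_medoids, cand_cost = _pam_swap(dist, init, max_iter)
        if cand_cost < best_cost - 1e-12:
            best_medoids, best_cost = cand_medoids, cand_cost
    labels = dist[:, best_medoids].argmin(axis=1)
    return labels, best_medoids


@dataclass
class ConsensusResult:
    """Consensus matrix plus derived labels and stability summaries."""

    consensus_matrix: np.ndarray
    labels: np.ndarray  # 1-based cluster per row
    cluster_consensus: dict[int, float]
    cdf_area: float
    spec: ModelSpec
    n_unseen_pairs: int = 0
    singleton_clusters: list[int] = field(default_factory=list)


def _cluster_once(X: np.ndarray, spec: ModelSpec, seed: int, n_init: int, max_iter: int) -> np.ndarray:
    if spec.algorithm == "kmeans":
        return kmeans_fit(X, spec.k, seed=seed, n_init=n_init, max_iter=max_iter)
    # a single extra SWAP restart is enough inside subsampled consensus runs
    labels, _ = pam_fit(X, spec.k, seed=seed, max_iter=max_iter, n_restarts=1)
    return labels


def consensus_cluster(
    X: np.ndarray,
    spec: ModelSpec,
    reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 100,
) -> ConsensusResult:
    """Subsampled consensus clustering of the rows of ``X`` under ``spec``."""
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if not 0.0 < p_item <= 1.0:
        raise ValueError("p_item must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    n = len(X)
    m = int(np.ceil(p_item * n))
    rng = np.random.default_rng(seed)

    # One indicator column per (rep, cluster); consensus counts then reduce to
    # two BLAS products instead of per-rep pairwise scatters.
    sampled = np.zeros((n, reps))
    member = np.zeros((n, reps * spec.k))
    for r in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        labels = _cluster_once(X[idx], spec, seed=int(rng.integers(2**31)), n_init=n_init, max_iter=max_iter)
        sampled[idx, r] = 1.0
        member[idx, r * spec.k + labels] = 1.0
    co_sample = sampled @ sampled.T
    co_cluster = member @ member.T

    iu = np.triu_indices(n, k=1)
    unseen = int((co_sample[iu] == 0).sum())
    if unseen > 0.01 * len(iu[0]):
        raise ValueError(
            f"insufficient reps: {unseen} of {len(iu[0])} pairs never co-sampled"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    labels = fcluster(
        linkage(squareform(1.0 - consensus, checks=False), method="average"),
        t=spec.k,
        criterion="maxclust",
    )
    cluster_consensus: dict[int, float] = {}
    singletons = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            cluster_consensus[int(c)] = 1.0  # no pairs: defined as 1, logged
            singletons.append(int(c))
            continue
        sub = consensus[np.ix_(members, members)]
        pair_vals = sub[np.triu_indices(len(members), k=1)]
        cluster_consensus[int(c)] = float(pair_vals.mean())
    if singletons:
        warnings.warn(f"singleton cluster(s) {singletons}: consensus defined as 1.0")

    # area under the empirical CDF of off-diagonal consensus values on [0, 1]
    cdf_area = float(1.0 - consensus[iu].mean())
    return ConsensusResult(
        consensus_matrix=consensus,
        labels=labels.astype(int),
        cluster_consensus=cluster_consensus,
        cdf_area=cdf_area,
        spec=spec,
        n_unseen_pairs=unseen,
        singleton_clusters=singletons,
    )


def consensus_cdf_deltas(results: dict[int, ConsensusResult]) -> dict[int, float]:
    """Relative change in consensus-CDF area per k (raw area for the first k)."""
    ks = sorted(results)
    if len(ks) < 2:
        raise ValueError("need results for at least two values of k")
    if ks[0] != 2 or ks != list(range(2, 2 + len(ks))):
        raise ValueError("results must cover consecutive k starting at 2")
    areas = {k: results[k].cdf_area for k in ks}
    deltas = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
    return deltas


def cdf_k_selection(results: dict[int, ConsensusResult], threshold: float = 0.1) -> int:
    """Choose k from the relative change in consensus-CDF area across k.

    ``results`` must cover consecutive k starting at 2.  Because a random
    k-way partition already co-clusters a pair w.p. ~1/k, the CDF area grows
    mechanically with k even on structureless data: the expected area is
    ~1 − 1/k, so the null relative gain at k is 1/(k(k−2)).  A value of k is
    a candidate when its observed relative gain exceeds that null baseline by
    more than ``threshold``; the largest candidate wins, with a fallback to
    k=2 (and a warning) when no k shows a genuine gain.
    """
    deltas = consensus_cdf_deltas(results)
    ks = sorted(deltas)
    above = [k for k in ks if k >= 3 and deltas[k] - 1.0 / (k * (k - 2)) > threshold]
    if above:
        return max(above)
    warnings.warn("no k shows a consensus-CDF gain beyond the null baseline; falling back to k=2")
    return 2


def write_consensus_csv(result: ConsensusResult, ids: list[str], path) -> None:
    pd.DataFrame(result.consensus_matrix, index=ids, columns=ids).to_csv(path)


def write_labels_csv(result: ConsensusResult, ids: list[str], path) -> None:
    pd.DataFrame({"patient_id": ids, "phenotype": result.labels}).to_csv(path, index=False)
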