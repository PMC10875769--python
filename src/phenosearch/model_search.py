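"""Candidate-model enumeration, stability and efficacy gating, and selection.

Every variable subset in the requested size range is crossed with the
clustering algorithms.  A candidate passes the stability gate when every
cluster's consensus score exceeds 0.90, and the efficacy gate when at least
one phenotype shows a significant (two-sided log-rank p < 0.05) reduction of
composite events in the active arm.  Among passing candidates the one with
the smallest benefiting-phenotype p wins, with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .consensus_clustering import ConsensusResult, ModelSpec, consensus_cluster
from .outcomes_stats import derive_make90_table, logrank_test
from .preprocessing import PrepConfig, prepare_matrix

CONSENSUS_GATE = 0.90
EFFICACY_ALPHA = 0.05


@dataclass
class ClusteringParams:
    reps: int = 1000
    p_item: float = 0.8
    n_init: int = 5
    max_iter: int = 100


@dataclass
class PhenotypeEfficacy:
    phenotype: int
    n_active: int
    n_placebo: int
    incidence_active: float
    incidence_placebo: float
    p_value: float | None
    note: str = ""

    @property
    def benefit(self) -> bool:
        return (
            self.p_value is not None
            and self.p_value < EFFICACY_ALPHA
            and self.incidence_active < self.incidence_placebo
        )


@dataclass
class ModelEvaluation:
    spec: ModelSpec
    n_used: int
    cluster_consensus: dict[int, float]
    gate_consensus: bool
    phenotypes: list[PhenotypeEfficacy]
    gate_efficacy: bool
    labels: np.ndarray = field(repr=False, default=None)
    ids: list[str] = field(repr=False, default_factory=list)
    consensus: ConsensusResult = field(repr=False, default=None)

    @property
    def benefiting(self) -> PhenotypeEfficacy | None:
        winners = [p for p in self.phenotypes if p.benefit]
        if not winners:
            return None
        return min(winners, key=lambda p: p.p_value)

    @property
    def rank_key(self) -> tuple:
        """Sort key for :func:`select_best` — smaller is better."""
        b = self.benefiting
        if b is None:
            return (np.inf, 0.0, len(self.spec.variables), self.spec.variables, self.spec.algorithm)
        gap = abs(b.incidence_placebo - b.incidence_active)
        return (b.p_value, -gap, len(self.spec.variables), self.spec.variables, self.spec.algorithm)


def enumerate_models(
    variables: list[str],
    size_range: tuple[int, int] = (2, 5),
    algorithms: tuple[str, ...] = ("kmeans", "pam"),
    k_set: tuple[int, ...] = (2,),
    allow_singletons: bool = False,
) -> list[ModelSpec]:
    """All variable subsets in the size range crossed with algorithms and k."""
    if not variables:
        raise ValueError("empty variable list")
    lo, hi = size_range
    min_size = 1 if allow_singletons else 2
    if lo < min_size or hi > len(variables) or lo > hi:
        raise ValueError(f"size_range must lie within [{min_size}, {len(variables)}]")
    specs = []
    for size in range(lo, hi + 1):
        for combo in combinations(sorted(variables), size):
            for alg in sorted(algorithms):
                for k in sorted(k_set):
                    specs.append(ModelSpec(variables=combo, algorithm=alg, k=k))
    return specs


def evaluate_model(
    cohort: Cohort,
    spec: ModelSpec,
    params: ClusteringParams | None = None,
    seed: int = 0,
    prep_config: PrepConfig | None = None,
    prepared=None,
) -> ModelEvaluation:
    """Preprocess, consensus-cluster and gate one candidate model.

    ``prepared`` lets callers reuse a :class:`PreparedMatrix` across the two
    algorithms of the same variable subset.
    """
    params = params or ClusteringParams()
    if prepared is None:
        prepared = prepare_matrix(cohort, list(spec.variables), seed=seed, config=prep_config)
    result = consensus_cluster(
        prepared.X.to_numpy(),
        spec,
        reps=params.reps,
        p_item=params.p_item,
        seed=seed,
        n_init=params.n_init,
        max_iter=params.max_iter,
    )
    gate_consensus = all(v > CONSENSUS_GATE for v in result.cluster_consensus.values())

    retained = cohort.data.set_index("patient_id").loc[prepared.ids].reset_index()
    retained_cohort = Cohort(retained, list(cohort.baseline_vars))
    outcomes = derive_make90_table(retained_cohort)
    arms = retained["arm"].to_numpy()

    phenotypes = []
    for ph in sorted(np.unique(result.labels)):
        in_ph = result.labels == ph
        act = in_ph & (arms == "active")
        pla = in_ph & (arms == "placebo")
        o_act = outcomes.loc[act]
        o_pla = outcomes.loc[pla]
        inc_a = float(o_act["event"].mean()) if len(o_act) else float("nan")
        inc_p = float(o_pla["event"].mean()) if len(o_pla) else float("nan")
        if len(o_act) < 2 or len(o_pla) < 2:
            phenotypes.append(
                PhenotypeEfficacy(int(ph), int(act.sum()), int(pla.sum()), inc_a, inc_p,
                                  p_value=None, note="fewer than 2 patients in an arm")
            )
            continue
        try:
            lr = logrank_test(o_act, o_pla)
            p_val, note = lr.p_value, ""
        except ValueError as exc:
            p_val, note = None, str(exc)
        phenotypes.append(
            PhenotypeEfficacy(int(ph), int(act.sum()), int(pla.sum()), inc_a, inc_p, p_val, note)
        )

    return ModelEvaluation(
        spec=spec,
        n_used=len(prepared.ids),
        cluster_consensus=result.cluster_consensus,
        gate_consensus=gate_consensus,
        phenotypes=phenotypes,
        gate_efficacy=any(p.benefit for p in phenotypes),
        labels=result.labels,
        ids=prepared.ids,
        consensus=result,
    )


def search_models(
    cohort: Cohort,
    variables: list[str],
    size_range: tuple[int, int] = (2, 5),
    algorithms: tuple[str, ...] = ("kmeans", "pam"),
    params: ClusteringParams | None = None,
    seed: int = 0,
    prep_config: PrepConfig | None = None,
) -> list[ModelEvaluation]:
    """Evaluate every enumerated candidate model; deterministic given the seed.

    Preprocessing is shared across algorithms for the same variable subset.
    """
    specs = enumerate_models(variables, size_range=size_range, algorithms=algorithms)
    prep_cache: dict[tuple[str, ...], object] = {}
    out = []
    for spec in specs:
        if spec.variables not in prep_cache:
            prep_cache[spec.variables] = prepare_matrix(
                cohort, list(spec.variables), seed=seed, config=prep_config
            )
        out.append(
            evaluate_model(
                cohort, spec, params=params, seed=seed,
                prep_config=prep_config, prepared=prep_cache[spec.variables],
            )
        )
    return out


def select_best(evaluations: list[ModelEvaluation]) -> ModelEvaluation:
    """Pick the passing model with the strongest treatment separation.

    Ordering: smallest benefiting-phenotype log-rank p, then largest absolute
    incidence difference, then fewer variables, then lexicographic spec order.
    """
    passing = [e for e in evaluations if e.gate_consensus and e.gate_efficacy]
    if not passing:
        raise ValueError("no model passes gates")
    return min(passing, key=lambda e: e.rank_key)


def evaluations_table(evaluations: list[ModelEvaluation]) -> pd.DataFrame:
    """One row per evaluation, suitable for CSV export."""
    rows = []
    for e in evaluations:
        b = e.benefiting
        rows.append(
            {
                "variables": "+".join(e.spec.variables),
                "algorithm": e.spec.algorithm,
                "k": e.spec.k,
                "n_used": e.n_used,
                "min_cluster_consensus": min(e.cluster_consensus.values()),
                "gate_consensus": e.gate_consensus,
                "gate_efficacy": e.gate_efficacy,
                "benefit_phenotype": b.phenotype if b else None,
                "benefit_p": b.p_value if b else None,
                "benefit_incidence_gap": (
                    b.incidence_placebo - b.incidence_active if b else None
                ),
            }
        )
    return pd.DataFrame(rows)
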