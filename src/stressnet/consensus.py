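"""Grouped arc-weight ensemble aggregation.

Because simulated annealing is stochastic, repeated searches return
slightly different consensus networks. The aggregation procedure runs the
learner many times (1000 at study scale), divides the resulting consensus
networks into groups (10 groups of 100), counts per group how many member
networks contain each arc (the arc "weight", 1..group_size), and finally
selects the arcs whose mean weight across groups clears a threshold
(inclusive; 50 of 100 at study scale). Variables left without any selected
arc are excluded from the final node list but reported as isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from ._seeds import derive_seed
from .datasets import DiscreteDataset
from .errors import ConfigError, DataError
from .structure import (
    BDeScorer,
    SearchConfig,
    consensus_of_top,
    simulated_annealing_search,
)
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)


@dataclass
class ArcWeightMatrix:
    """Per-group arc weights: weight(arc) = member networks containing it."""

    group_id: int
    weights: dict[tuple[str, str], int]

    def __post_init__(self):
        for arc, w in self.weights.items():
            if w < 1:
                raise DataError(f"arc {arc} listed with weight {w} < 1")


@dataclass
class FinalNetwork:
    """The selected network plus bookkeeping of dropped variables.

    ``graph`` contains only non-isolated nodes; edges carry ``mean_weight``.
    ``variables`` is the full input roster, ``isolated`` the variables with
    no selected arc.
    """

    graph: nx.DiGraph
    variables: list[str] = field(default_factory=list)
    isolated: list[str] = field(default_factory=list)
    selection_rule: str = "mean"
    threshold: float = 0.0


def run_ensemble(
    data: DiscreteDataset,
    cfg: SearchConfig,
    n_runs: int,
    master_seed: int,
    majority_fraction: float = 0.5,
) -> list[nx.DiGraph]:
    """Run ``n_runs`` independent searches, each reduced to a consensus graph.

    Run i uses a sub-seed derived from ``master_seed`` and i, so the
    ensemble is reproducible and runs are uncorrelated. The BDeu family
    cache is shared across runs (same data, same prior).
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    scorer = BDeScorer(data, cfg.ess)
    out = []
    for i in range(n_runs):
        run_cfg = SearchConfig(**{**cfg.__dict__, "seed": derive_seed(master_seed, "run", i)})
        top = simulated_annealing_search(data, run_cfg, scorer=scorer)
        out.append(consensus_of_top(top, majority_fraction))
    return out


def group_and_weight(
    networks: list[nx.DiGraph], group_size: int
) -> list[ArcWeightMatrix]:
    """Split run-ordered networks into groups and count arcs per group."""
    if group_size < 1:
        raise ConfigError("group_size must be >= 1")
    if len(networks) % group_size != 0:
        raise DataError(
            f"{len(networks)} networks not divisible into groups of {group_size}"
        )
    matrices = []
    for g in range(len(networks) // group_size):
        members = networks[g * group_size : (g + 1) * group_size]
        weights: dict[tuple[str, str], int] = {}
        for net in members:
            for e in net.edges():
                weights[e] = weights.get(e, 0) + 1
        matrices.append(ArcWeightMatrix(group_id=g, weights=weights))
    return matrices


def select_arcs(
    matrices: list[ArcWeightMatrix],
    threshold: float,
    variables: list[str] | None = None,
    rule: str = "mean",
    min_groups: int | None = None,
) -> FinalNetwork:
    """Build the final network from grouped arc weights.

    rule="mean" (default): an arc is selected iff its mean weight across
    all groups (0 where absent) is >= threshold (inclusive).
    rule="groups": an arc is selected iff its weight is >= threshold in at
    least ``min_groups`` groups.

    If both directions of an edge pass, only the higher-mean direction is
    kept (ties: lexicographically smaller parent, logged). Variables with
    no selected arc are dropped from the graph but listed in ``isolated``.
    """
    if not matrices:
        raise DataError("need at least one arc-weight matrix")
    if rule not in ("mean", "groups"):
        raise ConfigError(f"unknown selection rule '{rule}'")
    n_groups = len(matrices)
    arcs = sorted({a for m in matrices for a in m.weights})
    mean_w = {
        a: sum(m.weights.get(a, 0) for m in matrices) / n_groups for a in arcs
    }
    if rule == "mean":
        selected = {a for a in arcs if mean_w[a] >= threshold}
    else:
        k = n_groups if min_groups is None else min_groups
        selected = {
            a
            for a in arcs
            if sum(m.weights.get(a, 0) >= threshold for m in matrices) >= k
        }
    # resolve doubly-selected edges to one direction
    for u, v in sorted(selected):
        if (v, u) in selected and (u, v) in selected:
            if mean_w[(u, v)] > mean_w[(v, u)]:
                selected.discard((v, u))
            elif mean_w[(u, v)] < mean_w[(v, u)]:
                selected.discard((u, v))
            else:
                keep = min((u, v), (v, u))
                drop = (keep[1], keep[0])
                selected.discard(drop)
                log.info(
                    "both directions of %s-%s tie at mean weight %.3f; kept %s",
                    u, v, mean_w[(u, v)], keep,
                )
    g = nx.DiGraph()
    for a in sorted(selected):
        g.add_edge(*a, mean_weight=mean_w[a])
    roster = list(variables) if variables is not None else sorted(
        {x for a in arcs for x in a}
    )
    linked = set(g.nodes())
    isolated = [v for v in roster if v not in linked]
    return FinalNetwork(
        graph=g,
        variables=roster,
        isolated=isolated,
        selection_rule=rule,
        threshold=threshold,
    )


class ConsensusNetworkEnsemble(BaseEstimator):
    """End-to-end ensemble structure learner (scikit-learn style).

    ``fit(X)`` runs ``n_runs`` annealed searches on a discrete dataset,
    groups the per-run consensus networks, weights arcs, and selects the
    final network.

    Attributes
    ----------
    networks_ : per-run consensus graphs.
    weight_matrices_ : list of :class:`ArcWeightMatrix`.
    final_network_ : :class:`FinalNetwork`.
    """

    def __init__(
        self,
        n_runs: int = 50,
        group_size: int = 5,
        threshold: float | None = None,
        rule: str = "mean",
        min_groups: int | None = None,
        majority_fraction: float = 0.5,
        n_proposals: int = 100_000,
        top_n: int = 100,
        ess: float = 1.0,
        initial_temperature: float = 1e4,
        cooling_factor: float = 0.9,
        proposals_per_level: int = 2500,
        reanneal_after: int = 5000,
        max_parents: int | None = None,
        seed: int = 0,
    ):
        self.n_runs = n_runs
        self.group_size = group_size
        self.threshold = threshold
        self.rule = rule
        self.min_groups = min_groups
        self.majority_fraction = majority_fraction
        self.n_proposals = n_proposals
        self.top_n = top_n
        self.ess = ess
        self.initial_temperature = initial_temperature
        self.cooling_factor = cooling_factor
        self.proposals_per_level = proposals_per_level
        self.reanneal_after = reanneal_after
        self.max_parents = max_parents
        self.seed = seed

    def fit(self, X, y=None):
        from .structure import BayesianNetworkLearner

        ds = BayesianNetworkLearner._as_dataset(X)
        cfg = SearchConfig(
            n_proposals=self.n_proposals,
            top_n=self.top_n,
            ess=self.ess,
            initial_temperature=self.initial_temperature,
            cooling_factor=self.cooling_factor,
            proposals_per_level=self.proposals_per_level,
            reanneal_after=self.reanneal_after,
            max_parents=self.max_parents,
            seed=self.seed,
        )
        self.networks_ = run_ensemble(
            ds, cfg, self.n_runs, self.seed, self.majority_fraction
        )
        self.weight_matrices_ = group_and_weight(self.networks_, self.group_size)
        thr = self.threshold if self.threshold is not None else self.group_size / 2
        self.final_network_ = select_arcs(
            self.weight_matrices_,
            thr,
            variables=ds.variables,
            rule=self.rule,
            min_groups=self.min_groups,
        )
        return self
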