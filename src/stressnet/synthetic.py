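"""Synthetic data generation with known ground truth.

Two families of generators:

* ground-truth Bayesian networks — a random DAG with categorical conditional
  probability tables drawn from symmetric Dirichlet priors, and ancestral
  sampling from it — used to test structure learning against a known graph;
* paired two-study RNA-seq-like count matrices — negative-binomial counts
  with a shared set of planted condition-responsive genes — used to test the
  differential-expression and intersection stages.

All generators are pure functions of their arguments including the seed; a
master seed spawns independent sub-streams per study via counter-based
derivation (see :mod:`stressnet._seeds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .datasets import CountMatrix, DiscreteDataset
from .errors import ConfigError, DataError


@dataclass
class GroundTruthBN:
    """A Bayesian network with known structure and categorical CPTs.

    ``cpts[v]`` has shape ``(q_v, r_v)`` where ``q_v`` is the number of joint
    parent configurations (product of parent arities, 1 for orphans) and
    ``r_v`` the node's arity; each row is a distribution over states. Parent
    configurations are indexed in mixed radix with the first listed parent
    most significant.
    """

    nodes: list[str]
    arities: dict[str, int]
    parents: dict[str, list[str]]
    cpts: dict[str, np.ndarray]

    def __post_init__(self):
        g = self.to_dag()
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("parent structure is cyclic")
        for v in self.nodes:
            r = self.arities[v]
            if r < 2:
                raise DataError(f"node '{v}' has arity {r} < 2")
            q = prod(self.arities[p] for p in self.parents.get(v, []))
            cpt = np.asarray(self.cpts[v], dtype=float)
            if cpt.shape != (q, r):
                raise DataError(
                    f"node '{v}': CPT shape {cpt.shape} != ({q}, {r})"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12, rtol=0):
                raise DataError(f"node '{v}': CPT rows do not sum to 1")

    def to_dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g


@dataclass
class TwoStudyDesign:
    """Design of a paired two-study negative-binomial count simulation.

    The two studies are independent experiments sharing a set of planted
    condition-responsive genes (``de_gene_ids``) whose group means differ by
    ``log2_fold_change``. Counts follow a negative binomial with variance
    mu + dispersion * mu^2 (standard RNA-seq parameterization). Per-gene
    baseline log-means (natural log) are uniform over
    ``baseline_log_mean_range``, spanning low- to high-expressed genes.

    Keep the planted fraction small (the default is 20 of 2000): the
    selection stage normalizes by plain library size, so a large mass of
    strongly shifted genes would induce composition bias in every null
    gene, as it would in real data analyzed without TMM-style correction.
    """

    n_genes: int = 2000
    n_samples_per_group: tuple[tuple[int, int], tuple[int, int]] = ((12, 13), (12, 13))
    de_gene_ids: frozenset = field(default_factory=frozenset)
    log2_fold_change: float = 4.0
    nb_dispersion: float = 0.05
    baseline_log_mean_range: tuple[float, float] = (np.log(5.0), np.log(500.0))
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for study in self.n_samples_per_group:
            if min(study) < 2:
                raise ConfigError("each group needs >= 2 samples")
        genes = set(self.gene_ids())
        if not set(self.de_gene_ids) <= genes:
            raise ConfigError("de_gene_ids must be a subset of the gene set")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def random_dag(n_nodes: int, max_parents: int, edge_prob: float, seed: int) -> nx.DiGraph:
    """Generate a random DAG with bounded in-degree.

    Nodes ``V0..V{n-1}`` are placed in a random topological order; each
    forward pair becomes an edge with probability ``edge_prob`` unless the
    child already has ``max_parents`` parents.
    """
    if n_nodes < 1:
        raise ConfigError("n_nodes must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise ConfigError("edge_prob must be in [0, 1]")
    rng = derive_rng(seed, "random_dag")
    names = [f"V{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for j in range(n_nodes):
        child = names[order[j]]
        n_par = 0
        for i in range(j):
            if n_par >= max_parents:
                break
            if rng.random() < edge_prob:
                g.add_edge(names[order[i]], child)
                n_par += 1
    return g


def random_cpts(
    dag: nx.DiGraph, arities: dict[str, int], concentration: float, seed: int
) -> GroundTruthBN:
    """Attach CPTs drawn from a symmetric Dirichlet to every node of a DAG.

    Small ``concentration`` yields near-deterministic rows. Gamma draws can
    all underflow to zero at extreme concentrations; such rows fall back to
    a uniformly chosen one-hot vector, the exact Dirichlet limit.
    """
    if concentration <= 0:
        raise ConfigError("concentration must be > 0")
    if any(a < 2 for a in arities.values()):
        raise ConfigError("all arities must be >= 2")
    rng = derive_rng(seed, "random_cpts")
    nodes = list(dag.nodes())
    parents = {v: sorted(dag.predecessors(v)) for v in nodes}
    cpts: dict[str, np.ndarray] = {}
    for v in nodes:
        r = arities[v]
        q = prod(arities[p] for p in parents[v])
        g = rng.standard_gamma(concentration, size=(q, r))
        sums = g.sum(axis=1)
        dead = sums == 0
        if dead.any():
            onehot = np.zeros((int(dead.sum()), r))
            onehot[np.arange(len(onehot)), rng.integers(0, r, size=len(onehot))] = 1.0
            g[dead] = onehot
            sums = g.sum(axis=1)
        cpts[v] = g / sums[:, None]
    return GroundTruthBN(nodes=nodes, arities=dict(arities), parents=parents, cpts=cpts)


def strong_cpts(
    dag: nx.DiGraph,
    arities: dict[str, int],
    peak: float = 0.9,
    seed: int = 0,
) -> GroundTruthBN:
    """CPTs with strong, identifiable parent-child dependence.

    Root nodes get a non-degenerate Dirichlet(5) marginal; each child row
    puts mass ``peak`` on the state ``(sum of parent states) mod r`` and
    spreads the rest evenly, so distinct parent configurations map to
    distinct preferred states and every edge carries signal. Use this
    (rather than a tiny Dirichlet concentration, which tends to make the
    roots themselves near-constant) when a recoverable ground truth is
    needed.
    """
    if not 0 < peak < 1:
        raise ConfigError("peak must be in (0, 1)")
    rng = derive_rng(seed, "strong_cpts")
    nodes = list(dag.nodes())
    parents = {v: sorted(dag.predecessors(v)) for v in nodes}
    cpts: dict[str, np.ndarray] = {}
    for v in nodes:
        r = arities[v]
        ps = parents[v]
        if not ps:
            cpts[v] = rng.dirichlet([5.0] * r)[None, :]
            continue
        q = prod(arities[p] for p in ps)
        cpt = np.full((q, r), (1.0 - peak) / (r - 1))
        for cfg in range(q):
            # decode mixed radix (first parent most significant)
            rem, states = cfg, []
            for p in reversed(ps):
                rem, s = divmod(rem, arities[p])
                states.append(s)
            cpt[cfg, sum(states) % r] = peak
        cpts[v] = cpt
    return GroundTruthBN(nodes=nodes, arities=dict(arities), parents=parents, cpts=cpts)


def _parent_config_codes(states: dict[str, np.ndarray], parents: list[str],
                         arities: dict[str, int]) -> np.ndarray:
    """Mixed-radix configuration index, first parent most significant."""
    n = len(next(iter(states.values()))) if states else 0
    if not parents:
        return np.zeros(n, dtype=np.int64)
    code = np.zeros_like(states[parents[0]], dtype=np.int64)
    for p in parents:
        code = code * arities[p] + states[p]
    return code


def sample_discrete(bn: GroundTruthBN, n_samples: int, seed: int) -> DiscreteDataset:
    """Draw samples from a ground-truth BN by ancestral sampling."""
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    rng = derive_rng(seed, "sample_discrete")
    order = list(nx.topological_sort(bn.to_dag()))
    states: dict[str, np.ndarray] = {}
    for v in order:
        cfg = _parent_config_codes(states, bn.parents.get(v, []), bn.arities)
        if cfg.size == 0:
            cfg = np.zeros(n_samples, dtype=np.int64)
        cum = np.cumsum(bn.cpts[v], axis=1)
        u = rng.random(n_samples)
        states[v] = (u[:, None] > cum[cfg, :]).sum(axis=1).astype(np.int64)
    data = pd.DataFrame(
        np.vstack([states[v] for v in bn.nodes]),
        index=bn.nodes,
        columns=[f"s{i}" for i in range(n_samples)],
    )
    labels = {v: [f"s{k}" for k in range(bn.arities[v])] for v in bn.nodes}
    return DiscreteDataset(data=data, arities=dict(bn.arities), labels=labels)


def simulate_two_study_counts(
    design: TwoStudyDesign,
) -> tuple[CountMatrix, CountMatrix, frozenset]:
    """Simulate two independent RNA-seq studies sharing planted DE genes.

    Returns the two count matrices and the planted gene set. Planted genes
    get a per-gene direction of effect (up or down in stress), shared across
    studies; non-planted genes have identical group means. Baseline
    abundances are drawn independently per study (the studies are separate
    experiments).
    """
    genes = design.gene_ids()
    de = frozenset(design.de_gene_ids) if design.log2_fold_change != 0 else frozenset()
    sign_rng = derive_rng(design.seed, "de_signs")
    signs = {g: (1.0 if sign_rng.random() < 0.5 else -1.0) for g in sorted(design.de_gene_ids)}
    matrices = []
    for s, (n0, n1) in enumerate(design.n_samples_per_group):
        rng = derive_rng(design.seed, "study", s)
        base = np.exp(
            rng.uniform(*design.baseline_log_mean_range, size=design.n_genes)
        )
        fc = np.ones(design.n_genes)
        for i, g in enumerate(genes):
            if g in design.de_gene_ids:
                fc[i] = 2.0 ** (signs[g] * design.log2_fold_change)
        mu = np.column_stack([np.tile(base, (n0, 1)).T, np.tile(base * fc, (n1, 1)).T])
        size = 1.0 / design.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
        samples = [f"S{s}_{i:03d}" for i in range(n0 + n1)]
        cond = pd.Series([0] * n0 + [1] * n1, index=samples)
        study = pd.Series([f"study{s}"] * (n0 + n1), index=samples)
        matrices.append(
            CountMatrix(
                pd.DataFrame(counts, index=genes, columns=samples), cond, study
            )
        )
    return matrices[0], matrices[1], de
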