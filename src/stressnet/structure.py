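"""Bayesian-network structure learning on discrete data.

Networks are scored with the BDeu marginal likelihood (the "uniform" BDe
variant): for node i with r_i states and q_i joint parent configurations,

    score_i = sum_j [lnG(a_ij) - lnG(a_ij + N_ij)]
            + sum_jk [lnG(a_ijk + N_ijk) - lnG(a_ijk)]

with a_ijk = ess / (r_i * q_i), a_ij = ess / q_i, N the data counts and
lnG the log-gamma function. The total log score decomposes over node
families, so a per-(node, parent-set) cache makes repeated scoring during
search cheap. The score assigns equal values to Markov-equivalent DAGs.

The searcher is simulated annealing over the space of DAGs with local
random moves — single-edge addition, deletion, or reversal, drawn uniformly
among the valid moves — starting from the empty graph, with geometric
cooling and re-annealing when acceptance stalls. The top-N distinct
structures ever visited are retained and can be reduced to a single
consensus graph by arc-frequency majority.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .datasets import DiscreteDataset
from .errors import ConfigError, DataError, NoMoveError


@dataclass
class ScoredNetwork:
    """A DAG together with its natural-log BDeu score."""

    dag: nx.DiGraph
    log_score: float


@dataclass
class SearchConfig:
    """Simulated-annealing search settings.

    ``n_proposals`` is the number of candidate networks examined (study
    scale 250e6; test scale ~1e5). ``top_n`` distinct structures are kept.
    Temperature starts at ``initial_temperature`` (score units) and is
    multiplied by ``cooling_factor`` every ``proposals_per_level``
    proposals; if no move is accepted for ``reanneal_after`` proposals the
    temperature resets to its initial value. ``initial_temperature=0``
    gives pure hill climbing (accept only non-worsening moves).
    """

    n_proposals: int = 100_000
    top_n: int = 100
    ess: float = 1.0
    initial_temperature: float = 1e4
    cooling_factor: float = 0.9
    proposals_per_level: int = 2500
    reanneal_after: int = 5000
    max_parents: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if not 0.0 < self.cooling_factor < 1.0:
            raise ConfigError("cooling_factor must be in (0, 1)")
        if self.ess <= 0:
            raise ConfigError("ess must be > 0")
        if self.n_proposals < 0:
            raise ConfigError("n_proposals must be >= 0")
        if self.initial_temperature < 0:
            raise ConfigError("initial_temperature must be >= 0")


class BDeScorer:
    """Decomposable BDeu scorer with a per-family cache.

    Family terms are keyed by (child, sorted parent tuple); repeated
    scoring during search, and across runs on the same dataset, reuses
    cached terms.
    """

    def __init__(self, data: DiscreteDataset, ess: float = 1.0):
        if ess <= 0:
            raise ConfigError("ess must be > 0")
        self.variables = list(data.variables)
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.arities = np.array([data.arities[v] for v in self.variables], dtype=np.int64)
        self.x = data.codes()
        self.n_samples = self.x.shape[1]
        self.ess = float(ess)
        self._cache: dict[tuple, float] = {}

    def family_score(self, child: int, parents: tuple[int, ...]) -> float:
        """Log BDeu term for one (child, parent-set) family (cached)."""
        key = (child, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        r = int(self.arities[child])
        if parents:
            q = 1.0
            code = np.zeros(self.n_samples, dtype=np.int64)
            for p in parents:
                a = int(self.arities[p])
                q *= a
                code = code * a + self.x[p]
        else:
            q = 1.0
            code = None
        a_jk = self.ess / (r * q)
        a_j = self.ess / q
        if self.n_samples == 0:
            term = 0.0
        elif code is None:
            counts = np.bincount(self.x[child], minlength=r)
            term = float(
                gammaln(a_j) - gammaln(a_j + self.n_samples)
                + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
            )
        else:
            full = code * r + self.x[child]
            _, cf = np.unique(full, return_counts=True)
            _, cj = np.unique(code, return_counts=True)
            term = float(
                (gammaln(a_j) - gammaln(a_j + cj)).sum()
                + (gammaln(a_jk + cf) - gammaln(a_jk)).sum()
            )
        self._cache[key] = term
        return term

    def score_parent_sets(self, parent_sets: list[tuple[int, ...]]) -> float:
        return sum(self.family_score(i, ps) for i, ps in enumerate(parent_sets))

    def score_dag(self, dag: nx.DiGraph) -> float:
        missing = [v for v in dag.nodes() if v not in self.index]
        if missing:
            raise DataError(f"nodes absent from data: {missing}")
        total = 0.0
        for v in dag.nodes():
            ps = tuple(sorted(self.index[p] for p in dag.predecessors(v)))
            total += self.family_score(self.index[v], ps)
        return total


def bde_score(dag: nx.DiGraph, data: DiscreteDataset, ess: float = 1.0) -> float:
    """Natural-log BDeu score of a DAG on a discrete dataset."""
    return BDeScorer(data, ess).score_dag(dag)


def _reaches(children: list[set], src: int, dst: int) -> bool:
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _valid_moves(nodes, edges, parents, children, max_parents):
    """Enumerate all valid (move_type, u, v) triples for a DAG state."""
    moves = []
    maxp = math.inf if max_parents is None else max_parents
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if (u, v) in edges:
                moves.append(("delete", u, v))
                # reversal u->v becomes v->u
                if len(parents[u]) < maxp:
                    children[u].discard(v)
                    ok = not _reaches(children, u, v)
                    children[u].add(v)
                    if ok:
                        moves.append(("reverse", u, v))
            else:
                if len(parents[v]) < maxp and not _reaches(children, v, u):
                    moves.append(("add", u, v))
    return moves


def propose_move(dag: nx.DiGraph, max_parents: int | None, rng) -> nx.DiGraph:
    """Return a neighbor DAG differing by one edge add / delete / reversal.

    The move is uniform among all valid moves; moves that would create a
    cycle or exceed ``max_parents`` are never produced. Raises
    :class:`NoMoveError` when no valid move exists.

    ``rng`` is a numpy Generator.
    """
    names = list(dag.nodes())
    index = {v: i for i, v in enumerate(names)}
    n = len(names)
    parents = [set() for _ in range(n)]
    children = [set() for _ in range(n)]
    edges = set()
    for a, b in dag.edges():
        u, v = index[a], index[b]
        edges.add((u, v))
        parents[v].add(u)
        children[u].add(v)
    moves = _valid_moves(range(n), edges, parents, children, max_parents)
    if not moves:
        raise NoMoveError("no valid local move")
    mtype, u, v = moves[int(rng.integers(len(moves)))]
    out = dag.copy()
    if mtype == "add":
        out.add_edge(names[u], names[v])
    elif mtype == "delete":
        out.remove_edge(names[u], names[v])
    else:
        out.remove_edge(names[u], names[v])
        out.add_edge(names[v], names[u])
    return out


def _edges_to_dag(names: list[str], edges: frozenset) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from((names[u], names[v]) for u, v in edges)
    return g


def simulated_annealing_search(
    data: DiscreteDataset, cfg: SearchConfig, scorer: BDeScorer | None = None
) -> list[ScoredNetwork]:
    """Anneal over DAG space; return the top-N distinct structures visited.

    Starts from the empty graph. Each step proposes a local move uniform
    among the valid ones; improvements are always accepted, worsenings with
    probability exp(delta / T). The returned list is sorted by descending
    score (ties broken by edge set for determinism); identical seeds and
    configs give identical output. A shared ``scorer`` may be passed to
    reuse the family cache across runs on the same dataset.
    """
    names = list(data.variables)
    n = len(names)
    if n < 2:
        raise DataError("need at least 2 variables to search over structures")
    if scorer is None:
        scorer = BDeScorer(data, cfg.ess)
    rng = random.Random(cfg.seed)
    maxp = n if cfg.max_parents is None else cfg.max_parents

    parent_sets: list[tuple[int, ...]] = [() for _ in range(n)]
    parents: list[set] = [set() for _ in range(n)]
    children: list[set] = [set() for _ in range(n)]
    edges: set = set()
    fam = [scorer.family_score(i, ()) for i in range(n)]
    score = sum(fam)

    visited: dict[frozenset, float] = {frozenset(): score}
    prune_at = max(4 * cfg.top_n, 512)

    pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    npairs = len(pairs)
    ncand = 3 * npairs
    fam_score = scorer.family_score

    t0 = cfg.initial_temperature
    anneal_start = 0
    since_accept = 0
    exhausted = False

    for step in range(cfg.n_proposals):
        if t0 > 0:
            level = (step - anneal_start) // cfg.proposals_per_level
            temp = t0 * cfg.cooling_factor**level
        else:
            temp = 0.0

        # rejection-sample a uniform valid move
        mtype = u = v = None
        for _ in range(8 * ncand):
            k = rng.randrange(ncand)
            t, pi = divmod(k, npairs)
            a, b = pairs[pi]
            if t == 0:  # add a->b
                if (a, b) in edges or (b, a) in edges:
                    continue
                if len(parents[b]) >= maxp or _reaches(children, b, a):
                    continue
                mtype, u, v = 0, a, b
                break
            elif t == 1:  # delete a->b
                if (a, b) not in edges:
                    continue
                mtype, u, v = 1, a, b
                break
            else:  # reverse a->b
                if (a, b) not in edges or len(parents[a]) >= maxp:
                    continue
                children[a].discard(b)
                ok = not _reaches(children, a, b)
                children[a].add(b)
                if not ok:
                    continue
                mtype, u, v = 2, a, b
                break
        if mtype is None:
            moves = _valid_moves(range(n), edges, parents, children, cfg.max_parents)
            if not moves:
                exhausted = True
                break
            name, u, v = moves[rng.randrange(len(moves))]
            mtype = {"add": 0, "delete": 1, "reverse": 2}[name]

        if mtype == 0:
            new_v = tuple(sorted(parents[v] | {u}))
            delta = fam_score(v, new_v) - fam[v]
        elif mtype == 1:
            new_v = tuple(sorted(parents[v] - {u}))
            delta = fam_score(v, new_v) - fam[v]
        else:
            new_v = tuple(sorted(parents[v] - {u}))
            new_u = tuple(sorted(parents[u] | {v}))
            delta = (
                fam_score(v, new_v) - fam[v] + fam_score(u, new_u) - fam[u]
            )

        accept = delta >= 0 or (temp > 0 and rng.random() < math.exp(delta / temp))
        if accept:
            if mtype == 0:
                edges.add((u, v))
                parents[v].add(u)
                children[u].add(v)
                fam[v] += delta
            elif mtype == 1:
                edges.discard((u, v))
                parents[v].discard(u)
                children[u].discard(v)
                fam[v] += delta
            else:
                edges.discard((u, v))
                edges.add((v, u))
                parents[v].discard(u)
                children[u].discard(v)
                parents[u].add(v)
                children[v].add(u)
                fam[v] = fam_score(v, new_v)
                fam[u] = fam_score(u, new_u)
            score += delta
            key = frozenset(edges)
            prev = visited.get(key)
            if prev is None:
                visited[key] = score
                if len(visited) > prune_at:
                    keep = sorted(visited.items(), key=lambda kv: -kv[1])[: 2 * cfg.top_n]
                    visited = dict(keep)
            since_accept = 0
        else:
            since_accept += 1
            if t0 > 0 and since_accept >= cfg.reanneal_after:
                anneal_start = step
                since_accept = 0

    del exhausted  # early stop leaves the visited set as the result
    ranked = sorted(
        visited.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )[: cfg.top_n]
    return [ScoredNetwork(_edges_to_dag(names, k), s) for k, s in ranked]


def enumerate_all_dags(n: int, nodes: list[str] | None = None) -> list[nx.DiGraph]:
    """Every labeled DAG on n nodes (n <= 4; 1, 3, 25, 543 graphs)."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if n > 4:
        raise ConfigError("exhaustive enumeration is limited to n <= 4")
    names = nodes if nodes is not None else [f"V{i}" for i in range(n)]
    if len(names) != n:
        raise ConfigError("len(nodes) must equal n")
    pairs = [(a, b) for a in range(n) for b in range(n) if a != b]
    out = []
    for mask in range(1 << len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for i, (a, b) in enumerate(pairs):
            if mask >> i & 1:
                g.add_edge(names[a], names[b])
        if nx.is_directed_acyclic_graph(g):
            out.append(g)
    return out


def consensus_of_top(
    top: list[ScoredNetwork], majority_fraction: float = 0.5
) -> nx.DiGraph:
    """Majority-vote consensus of a list of scored networks.

    An arc enters the consensus iff it appears in strictly more than
    ``majority_fraction`` of the networks; arcs carry their within-list
    frequency as the ``confidence`` edge attribute. The result need not be
    acyclic.
    """
    if not top:
        raise DataError("empty network list")
    if not 0 < majority_fraction <= 1:
        raise ConfigError("majority_fraction must be in (0, 1]")
    m = len(top)
    counts: dict[tuple, int] = {}
    for sn in top:
        for e in sn.dag.edges():
            counts[e] = counts.get(e, 0) + 1
    g = nx.DiGraph()
    g.add_nodes_from(top[0].dag.nodes())
    for (u, v), c in sorted(counts.items()):
        if c > majority_fraction * m:
            g.add_edge(u, v, confidence=c / m)
    return g


class BayesianNetworkLearner(BaseEstimator):
    """Simulated-annealing BDeu structure learner (scikit-learn style).

    ``fit(X)`` accepts a :class:`DiscreteDataset` or a samples x variables
    DataFrame/array of integer state codes (arities inferred as
    max code + 1, floor 2).

    Attributes
    ----------
    top_networks_ : list of :class:`ScoredNetwork`, best first.
    best_network_, best_score_ : the single highest-scoring structure.
    consensus_ : majority consensus of the top networks.
    """

    def __init__(
        self,
        n_proposals: int = 100_000,
        top_n: int = 100,
        ess: float = 1.0,
        initial_temperature: float = 1e4,
        cooling_factor: float = 0.9,
        proposals_per_level: int = 2500,
        reanneal_after: int = 5000,
        max_parents: int | None = None,
        majority_fraction: float = 0.5,
        seed: int = 0,
    ):
        self.n_proposals = n_proposals
        self.top_n = top_n
        self.ess = ess
        self.initial_temperature = initial_temperature
        self.cooling_factor = cooling_factor
        self.proposals_per_level = proposals_per_level
        self.reanneal_after = reanneal_after
        self.max_parents = max_parents
        self.majority_fraction = majority_fraction
        self.seed = seed

    def _config(self, seed=None) -> SearchConfig:
        return SearchConfig(
            n_proposals=self.n_proposals,
            top_n=self.top_n,
            ess=self.ess,
            initial_temperature=self.initial_temperature,
            cooling_factor=self.cooling_factor,
            proposals_per_level=self.proposals_per_level,
            reanneal_after=self.reanneal_after,
            max_parents=self.max_parents,
            seed=self.seed if seed is None else seed,
        )

    @staticmethod
    def _as_dataset(X) -> DiscreteDataset:
        if isinstance(X, DiscreteDataset):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            data = X.T
        else:
            X = np.asarray(X, dtype=np.int64)
            data = pd.DataFrame(
                X.T,
                index=[f"V{i}" for i in range(X.shape[1])],
                columns=[f"s{i}" for i in range(X.shape[0])],
            )
        arities = {
            v: max(2, int(data.loc[v].max()) + 1) for v in data.index
        }
        labels = {v: [f"s{k}" for k in range(arities[v])] for v in data.index}
        return DiscreteDataset(data=data, arities=arities, labels=labels)

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        self.top_networks_ = simulated_annealing_search(ds, self._config())
        self.best_network_ = self.top_networks_[0].dag
        self.best_score_ = self.top_networks_[0].log_score
        self.consensus_ = consensus_of_top(self.top_networks_, self.majority_fraction)
        return self
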