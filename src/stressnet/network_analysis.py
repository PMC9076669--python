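"""Interpretation of the final network.

Two lenses: the Markov blanket of the condition node (its parents, children
and spouses — the nodes that render it conditionally independent of the
rest of an acyclic network), and Girvan-Newman divisive community
detection — repeatedly removing the highest edge-betweenness edge of the
undirected skeleton and keeping the partition along the removal sequence
that maximizes Newman-Girvan modularity Q = sum_c (e_cc - a_c^2).

Betweenness and modularity computations delegate to networkx; the divisive
loop, deterministic tie-breaking and modularity-based cut are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from sklearn.base import BaseEstimator

from .errors import DataError


@dataclass
class MarkovBlanket:
    """Parents, children and spouses of a target node."""

    target: str
    parents: set
    children: set
    spouses: set

    @property
    def blanket(self) -> set:
        return self.parents | self.children | self.spouses


@dataclass
class CommunityPartition:
    """A node partition with its modularity and the removal dendrogram."""

    membership: dict
    modularity: float
    removal_sequence: list = field(default_factory=list)
    partitions: list = field(default_factory=list)  # (n_communities, membership, Q)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def community_of(self, node) -> set:
        if node not in self.membership:
            raise DataError(f"node '{node}' not in partition")
        cid = self.membership[node]
        return {n for n, c in self.membership.items() if c == cid}

    def cut(self, n_communities: int) -> dict:
        """First membership along the removal sequence with that many blocks."""
        for k, memb, _ in self.partitions:
            if k == n_communities:
                return dict(memb)
        raise DataError(f"no partition with {n_communities} communities in the dendrogram")


def markov_blanket(graph: nx.DiGraph, target) -> MarkovBlanket:
    """Graph-theoretic Markov blanket: parents, children, co-parents of children.

    On cyclic aggregate graphs the definition is applied literally;
    probabilistic-independence semantics hold only for DAGs.
    """
    if target not in graph:
        raise DataError(f"target '{target}' not in graph")
    parents = set(graph.predecessors(target))
    children = set(graph.successors(target))
    spouses = set()
    for c in children:
        spouses |= set(graph.predecessors(c))
    spouses.discard(target)
    return MarkovBlanket(target=target, parents=parents, children=children, spouses=spouses)


def edge_betweenness(graph: nx.Graph) -> dict:
    """Shortest-path edge betweenness over unordered node pairs.

    Equal-length paths contribute fractionally; a single edge between two
    otherwise disconnected nodes scores 1.
    """
    return dict(nx.edge_betweenness_centrality(graph, normalized=False))


def modularity(graph: nx.Graph, partition) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2) of a partition.

    ``partition`` is a node -> community-id mapping or an iterable of node
    sets. Edgeless graphs get Q = 0.
    """
    if isinstance(partition, dict):
        missing = [n for n in graph.nodes() if n not in partition]
        if missing:
            raise DataError(f"nodes missing from partition: {missing}")
        blocks: dict = {}
        for n, c in partition.items():
            blocks.setdefault(c, set()).add(n)
        communities = list(blocks.values())
    else:
        communities = [set(c) for c in partition]
        covered = set().union(*communities) if communities else set()
        missing = [n for n in graph.nodes() if n not in covered]
        if missing:
            raise DataError(f"nodes missing from partition: {missing}")
    if graph.number_of_edges() == 0:
        return 0.0
    return float(nx.community.modularity(graph, communities, weight=None))


def _components_membership(graph: nx.Graph) -> dict:
    memb = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for cid, comp in enumerate(comps):
        for n in comp:
            memb[n] = cid
    return memb


def girvan_newman(graph: nx.Graph) -> CommunityPartition:
    """Divisive edge-betweenness clustering with a modularity cut.

    Removes a maximum-betweenness edge (ties: lexicographically smallest
    edge), recomputing betweenness after every removal, down to the empty
    graph; returns the partition along the sequence maximizing modularity
    evaluated on the original graph (the no-removal partition included,
    first maximum wins). The full removal sequence and every distinct
    component structure are retained.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("empty graph")
    original = nx.Graph(graph)
    work = nx.Graph(graph)
    removal: list = []
    snapshots: list = []
    memb = _components_membership(work)
    q = modularity(original, memb)
    snapshots.append((len(set(memb.values())), memb, q))
    best_memb, best_q = memb, q
    while work.number_of_edges() > 0:
        eb = edge_betweenness(work)
        best_edge = min(
            eb.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
        )[0]
        best_edge = tuple(sorted(best_edge))
        work.remove_edge(*best_edge)
        removal.append(best_edge)
        memb = _components_membership(work)
        k = len(set(memb.values()))
        if not snapshots or k != snapshots[-1][0]:
            q = modularity(original, memb)
            snapshots.append((k, memb, q))
            if q > best_q:
                best_q, best_memb = q, memb
    return CommunityPartition(
        membership=dict(best_memb),
        modularity=best_q,
        removal_sequence=removal,
        partitions=snapshots,
    )


def condition_community(partition: CommunityPartition, target) -> set:
    """Members of the target's community, excluding the target itself."""
    return partition.community_of(target) - {target}


class GirvanNewmanCommunities(BaseEstimator):
    """Divisive community detection as an estimator.

    ``fit(G)`` takes an undirected graph (directed input is reduced to its
    undirected skeleton with unit weights).

    Attributes
    ----------
    labels_ : node -> community id of the modularity-optimal partition.
    modularity_ : its modularity.
    partition_ : the full :class:`CommunityPartition`.
    """

    def fit(self, X, y=None):
        g = X.to_undirected() if X.is_directed() else X
        self.partition_ = girvan_newman(g)
        self.labels_ = dict(self.partition_.membership)
        self.modularity_ = self.partition_.modularity
        return self
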