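"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute-force enumeration, hand-rolled
step-up procedures, textbook formulas — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the literal step-up recipe."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pooled_t(x0, x1):
    """Ordinary two-sample pooled-variance t statistic (group 1 minus 0)."""
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    n0, n1 = len(x0), len(x1)
    sp2 = (((x0 - x0.mean()) ** 2).sum() + ((x1 - x1.mean()) ** 2).sum()) / (
        n0 + n1 - 2
    )
    return (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))


def brute_edge_betweenness(g: nx.Graph) -> dict:
    """Edge betweenness by explicit enumeration of all shortest paths.

    For every unordered pair, enumerate every shortest path by recursive
    descent on the distance matrix; each path contributes 1/#paths to each
    edge it uses.
    """
    eb = {frozenset(e): 0.0 for e in g.edges()}
    dist = dict(nx.all_pairs_shortest_path_length(g))
    nodes = sorted(g.nodes())
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            paths = []

            def walk(u, path):
                if u == t:
                    paths.append(list(path))
                    return
                for w in g.neighbors(u):
                    if dist[w].get(t, -1) == dist[u][t] - 1:
                        path.append(w)
                        walk(w, path)
                        path.pop()

            walk(s, [s])
            share = 1.0 / len(paths)
            for path in paths:
                for a, b in zip(path, path[1:]):
                    eb[frozenset((a, b))] += share
    return {tuple(sorted(k)): v for k, v in eb.items()}


def brute_modularity(g: nx.Graph, membership: dict) -> float:
    """Q = sum_c (e_cc - a_c^2) evaluated from the definition."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    comms = set(membership.values())
    q = 0.0
    for c in comms:
        inside = sum(
            1 for u, v in g.edges() if membership[u] == c and membership[v] == c
        )
        ends = sum(
            sum(1 for e in g.edges(n)) for n in g.nodes() if membership[n] == c
        )
        q += inside / m - (ends / (2 * m)) ** 2
    return q


def v_structures(dag: nx.DiGraph) -> frozenset:
    """Colliders a->c<-b with a, b non-adjacent (unordered (a, b) plus c)."""
    out = set()
    for c in dag.nodes():
        ps = sorted(dag.predecessors(c))
        for i, a in enumerate(ps):
            for b in ps[i + 1 :]:
                if not dag.has_edge(a, b) and not dag.has_edge(b, a):
                    out.add((tuple(sorted((a, b))), c))
    return frozenset(out)


def skeleton(dag: nx.DiGraph) -> frozenset:
    return frozenset(frozenset(e) for e in dag.edges())


def markov_equivalence_key(dag: nx.DiGraph):
    """Two DAGs are Markov equivalent iff same skeleton and v-structures."""
    return (skeleton(dag), v_structures(dag))


def exact_joint(bn) -> dict:
    """Exact joint distribution of a small ground-truth BN by enumeration."""
    order = list(nx.topological_sort(bn.to_dag()))
    joint = {}
    for states in product(*(range(bn.arities[v]) for v in bn.nodes)):
        assign = dict(zip(bn.nodes, states))
        p = 1.0
        for v in order:
            cfg = 0
            for par in bn.parents.get(v, []):
                cfg = cfg * bn.arities[par] + assign[par]
            p *= bn.cpts[v][cfg, assign[v]]
        joint[states] = p
    return joint


def skeleton_f1(true_edges, est_edges) -> float:
    t = {frozenset(e) for e in true_edges}
    e = {frozenset(e) for e in est_edges}
    tp = len(t & e)
    if not e or not t or tp == 0:
        return 0.0
    prec, rec = tp / len(e), tp / len(t)
    return 2 * prec * rec / (prec + rec)
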