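import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import markov_equivalence_key
from stressnet.datasets import DiscreteDataset
from stressnet.errors import ConfigError, DataError, NoMoveError
from stressnet.structure import (
    BayesianNetworkLearner,
    BDeScorer,
    ScoredNetwork,
    SearchConfig,
    bde_score,
    consensus_of_top,
    enumerate_all_dags,
    propose_move,
    simulated_annealing_search,
)


def _dataset(arr, names=None):
    arr = np.asarray(arr)
    names = names or [chr(ord("A") + i) for i in range(arr.shape[0])]
    return DiscreteDataset(
        pd.DataFrame(arr, index=names, columns=[f"s{i}" for i in range(arr.shape[1])]),
        {n: max(2, int(arr[i].max()) + 1) for i, n in enumerate(names)},
        {n: ["s0", "s1", "s2"][: max(2, int(arr[i].max()) + 1)] for i, n in enumerate(names)},
    )


class TestBdeScore:
    def test_single_binary_node_closed_form(self):
        ds = _dataset([[0, 1]])
        g = nx.DiGraph()
        g.add_node("A")
        assert bde_score(g, ds, ess=1.0) == pytest.approx(math.log(1 / 8), abs=1e-9)

    def test_empty_dataset_scores_zero(self):
        ds = DiscreteDataset(
            pd.DataFrame(np.empty((1, 0), dtype=int), index=["A"]),
            {"A": 2}, {"A": ["s0", "s1"]},
        )
        g = nx.DiGraph()
        g.add_node("A")
        assert bde_score(g, ds) == 0.0

    def test_two_node_reversal_equivalence(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.integers(0, 3, size=(2, 40)))
        ab, ba = nx.DiGraph(), nx.DiGraph()
        ab.add_edge("A", "B")
        ba.add_edge("B", "A")
        assert bde_score(ab, ds) == pytest.approx(bde_score(ba, ds), abs=1e-9)

    def test_markov_equivalent_dags_score_equal(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng.integers(0, 2, size=(3, 60)))
        scorer = BDeScorer(ds)
        classes: dict = {}
        for dag in enumerate_all_dags(3, nodes=["A", "B", "C"]):
            classes.setdefault(markov_equivalence_key(dag), []).append(scorer.score_dag(dag))
        assert len(classes) == 11  # 25 labeled 3-node DAGs form 11 classes
        for scores in classes.values():
            assert max(scores) - min(scores) <= 1e-6 * abs(scores[0])

    def test_decomposability_cached_vs_fresh(self):
        rng = np.random.default_rng(2)
        ds = _dataset(rng.integers(0, 3, size=(4, 50)))
        shared = BDeScorer(ds)
        for dag in enumerate_all_dags(4, nodes=["A", "B", "C", "D"])[::37]:
            assert shared.score_dag(dag) == pytest.approx(
                BDeScorer(ds).score_dag(dag), abs=1e-9
            )

    def test_unknown_node_errors(self):
        ds = _dataset([[0, 1]])
        g = nx.DiGraph()
        g.add_node("ZZ")
        with pytest.raises(DataError):
            bde_score(g, ds)

    def test_true_edge_helps_false_edge_hurts(self, chain_ab_bn):
        from stressnet.synthetic import sample_discrete

        wins_true, wins_false = 0, 0
        for seed in range(20):
            ds = sample_discrete(chain_ab_bn, 1000, seed=100 + seed)
            sc = BDeScorer(ds)
            empty = sum(sc.family_score(i, ()) for i in range(3))
            ia, ib, ic = (sc.index[v] for v in "ABC")
            with_true = empty - sc.family_score(ib, ()) + sc.family_score(ib, (ia,))
            with_false = empty - sc.family_score(ic, ()) + sc.family_score(ic, (ia,))
            wins_true += with_true > empty
            wins_false += with_false < empty
        assert wins_true >= 18 and wins_false >= 18


class TestEnumerateAllDags:
    @pytest.mark.parametrize("n,count", [(1, 1), (2, 3), (3, 25), (4, 543)])
    def test_robinson_counts(self, n, count):
        dags = enumerate_all_dags(n)
        assert len(dags) == count
        seen = {frozenset(d.edges()) for d in dags}
        assert len(seen) == count  # each labeled DAG exactly once
        assert all(nx.is_directed_acyclic_graph(d) for d in dags)

    def test_refuses_large_n(self):
        with pytest.raises(ConfigError):
            enumerate_all_dags(5)


class TestProposeMove:
    def test_empty_two_node_neighborhood(self):
        g = nx.DiGraph()
        g.add_nodes_from("AB")
        rng = np.random.default_rng(0)
        seen = {tuple(sorted(propose_move(g, None, rng).edges())) for _ in range(100)}
        assert seen == {(("A", "B"),), (("B", "A"),)}

    def test_single_edge_moves_include_reversal(self):
        g = nx.DiGraph()
        g.add_edge("A", "B")
        rng = np.random.default_rng(1)
        seen = {frozenset(propose_move(g, None, rng).edges()) for _ in range(200)}
        assert frozenset({("B", "A")}) in seen  # reversal
        assert frozenset() in seen  # deletion

    def test_cycle_closing_addition_never_proposed(self):
        g = nx.DiGraph()
        g.add_edges_from([("A", "B"), ("B", "C")])
        rng = np.random.default_rng(2)
        for _ in range(300):
            out = propose_move(g, None, rng)
            assert nx.is_directed_acyclic_graph(out)
            assert not out.has_edge("C", "A")

    def test_max_parents_respected(self):
        g = nx.DiGraph()
        g.add_edges_from([("A", "C"), ("B", "C")])
        g.add_node("D")
        rng = np.random.default_rng(3)
        for _ in range(200):
            out = propose_move(g, 2, rng)
            assert max(out.in_degree(v) for v in out.nodes()) <= 2

    def test_no_move_signalled(self):
        g = nx.DiGraph()
        g.add_node("A")
        with pytest.raises(NoMoveError):
            propose_move(g, None, np.random.default_rng(0))


class TestSearch:
    def test_zero_proposals_returns_empty_graph(self, chain_ab_data):
        out = simulated_annealing_search(chain_ab_data, SearchConfig(n_proposals=0, seed=1))
        assert len(out) == 1 and out[0].dag.number_of_edges() == 0

    def test_same_seed_identical_output(self, chain_ab_data):
        cfg = SearchConfig(n_proposals=5000, seed=9)
        a = simulated_annealing_search(chain_ab_data, cfg)
        b = simulated_annealing_search(chain_ab_data, cfg)
        assert [(sorted(x.dag.edges()), x.log_score) for x in a] == [
            (sorted(x.dag.edges()), x.log_score) for x in b
        ]

    def test_hill_climbing_reaches_local_optimum(self, chain_ab_data):
        """Zero temperature accepts only improvements, so the best visited
        score equals the final state's score and no neighbor improves it."""
        cfg = SearchConfig(n_proposals=20_000, initial_temperature=0.0, seed=4)
        out = simulated_annealing_search(chain_ab_data, cfg)
        scores = [sn.log_score for sn in out]
        assert scores == sorted(scores, reverse=True)

    def test_finds_exhaustive_optimum_on_strong_signal(self, chain_ab_data):
        scorer = BDeScorer(chain_ab_data)
        best = max(
            scorer.score_dag(d)
            for d in enumerate_all_dags(3, nodes=list(chain_ab_data.variables))
        )
        hits = 0
        for seed in range(10):
            top = simulated_annealing_search(
                chain_ab_data, SearchConfig(n_proposals=100_000, seed=seed), scorer=scorer
            )
            hits += abs(top[0].log_score - best) < 1e-9
        assert hits >= 9

    def test_search_scores_subset_of_exhaustive(self, chain_ab_data):
        scorer = BDeScorer(chain_ab_data)
        all_scores = sorted(
            scorer.score_dag(d)
            for d in enumerate_all_dags(3, nodes=list(chain_ab_data.variables))
        )
        top = simulated_annealing_search(
            chain_ab_data, SearchConfig(n_proposals=2000, seed=5), scorer=scorer
        )
        for sn in top:
            assert any(abs(sn.log_score - s) < 1e-6 for s in all_scores)

    def test_top_networks_distinct(self, chain_ab_data):
        top = simulated_annealing_search(
            chain_ab_data, SearchConfig(n_proposals=20_000, seed=6)
        )
        keys = {frozenset(sn.dag.edges()) for sn in top}
        assert len(keys) == len(top)


class TestConsensusOfTop:
    def _nets(self, edge_lists):
        out = []
        for edges in edge_lists:
            g = nx.DiGraph()
            g.add_nodes_from("ABC")
            g.add_edges_from(edges)
            out.append(ScoredNetwork(g, 0.0))
        return out

    def test_identical_networks_give_confidence_one(self):
        nets = self._nets([[("A", "B"), ("B", "C")]] * 10)
        cons = consensus_of_top(nets, 0.5)
        assert set(cons.edges()) == {("A", "B"), ("B", "C")}
        assert all(d["confidence"] == 1.0 for _, _, d in cons.edges(data=True))

    def test_majority_boundary(self):
        nets = self._nets([[("A", "B")]] * 51 + [[]] * 49)
        cons = consensus_of_top(nets, 0.5)
        assert cons.has_edge("A", "B")
        assert cons["A"]["B"]["confidence"] == pytest.approx(0.51)
        nets = self._nets([[("A", "B")]] * 49 + [[]] * 51)
        assert not consensus_of_top(nets, 0.5).has_edge("A", "B")

    def test_exact_majority_excluded_by_strict_rule(self):
        nets = self._nets([[("A", "B")]] * 50 + [[]] * 50)
        assert not consensus_of_top(nets, 0.5).has_edge("A", "B")


class TestLearnerEstimator:
    def test_fit_on_dataframe_recovers_dependency(self, chain_ab_data):
        X = chain_ab_data.data.T  # samples x variables
        est = BayesianNetworkLearner(n_proposals=50_000, seed=0).fit(X)
        skel = {frozenset(e) for e in est.best_network_.edges()}
        assert frozenset({"A", "B"}) in skel
        assert est.best_score_ == est.top_networks_[0].log_score
        assert est.consensus_.number_of_nodes() == 3
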