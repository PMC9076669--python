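import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup, pooled_t
from stressnet.datasets import CountMatrix
from stressnet.deselect import (
    ModeratedTSelector,
    adjust_bh,
    filter_low_counts,
    fit_moderated_t,
    intersect_gene_lists,
    log_cpm,
    top_genes,
)
from stressnet.errors import ConfigError, DataError
from stressnet.synthetic import TwoStudyDesign, simulate_two_study_counts


class TestFilterLowCounts:
    def test_zero_row_removed(self, tiny_counts):
        out = filter_low_counts(tiny_counts, min_cpm=0.1, min_samples=1)
        assert "g2" not in out.genes and out.samples == tiny_counts.samples

    def test_vacuous_filter_is_identity(self, tiny_counts):
        out = filter_low_counts(tiny_counts, min_cpm=0.0, min_samples=0)
        assert out.genes == tiny_counts.genes

    def test_cpm_arithmetic_at_threshold(self):
        counts = pd.DataFrame({"s1": [1, 99], "s2": [0, 100]}, index=["g1", "g2"])
        cm = CountMatrix(counts, pd.Series([0, 1], index=["s1", "s2"]))
        # g1: CPM 10000 in s1 (1/100 * 1e6); kept at min_cpm=5000 in >=1 sample
        out = filter_low_counts(cm, min_cpm=5000, min_samples=1)
        assert "g1" in out.genes

    def test_min_samples_bound(self, tiny_counts):
        with pytest.raises(ConfigError):
            filter_low_counts(tiny_counts, 1.0, min_samples=99)


class TestLogCpm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        counts.loc["h"] = [999]
        cm = CountMatrix(counts, pd.Series([0], index=["s1"]),
                         pd.Series(["x"], index=["s1"]))
        out = log_cpm(cm, prior_count=0.5)
        assert out.loc["g", "s1"] == pytest.approx(np.log2(0.5 / 1000 * 1e6), abs=1e-9)

    def test_unlogged_cpm_sums_to_million(self, tiny_counts):
        out = log_cpm(tiny_counts, prior_count=0.0)
        cpm = np.power(2.0, out.to_numpy())
        np.testing.assert_allclose(np.nansum(np.where(np.isfinite(cpm), cpm, 0), axis=0),
                                   1e6, rtol=1e-9)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [0], "s2": [5]}, index=["g"])
        cm = CountMatrix(counts, pd.Series([0, 1], index=["s1", "s2"]))
        with pytest.raises(DataError):
            log_cpm(cm, 0.5)


class TestModeratedT:
    def test_hand_computed_pooled_t(self):
        lm = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("wxyz"))
        st_ = fit_moderated_t(lm, [0, 0, 1, 1], d0=0)
        assert st_.loc["g", "log2fc"] == pytest.approx(2.0)
        assert st_.loc["g", "s2"] == pytest.approx(0.5)
        assert st_.loc["g", "t"] == pytest.approx(2.8284, abs=1e-4)

    def test_d0_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 10))
        lm = pd.DataFrame(x, index=[f"g{i}" for i in range(40)])
        cond = np.array([0] * 5 + [1] * 5)
        st_ = fit_moderated_t(lm, cond, d0=0)
        for i in range(40):
            expected = pooled_t(x[i, :5], x[i, 5:])
            assert st_["t"].iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_identical_groups_give_zero_t(self):
        lm = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"])
        st_ = fit_moderated_t(lm, [0, 0, 1, 1])
        assert st_.loc["g", "log2fc"] == 0 and st_.loc["g", "t"] == 0

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(3)
        lm = pd.DataFrame(rng.normal(size=(200, 12)) * rng.uniform(0.5, 2, size=(200, 1)))
        st_ = fit_moderated_t(lm, np.repeat([0, 1], 6))
        s0 = st_.attrs["s0_squared"]
        lo = np.minimum(st_["s2"], s0)
        hi = np.maximum(st_["s2"], s0)
        assert ((st_["s2_post"] >= lo - 1e-12) & (st_["s2_post"] <= hi + 1e-12)).all()

    def test_constant_gene_gets_positive_posterior_variance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 8))
        x[0] = 1.0  # all-constant gene: s2 = 0
        st_ = fit_moderated_t(pd.DataFrame(x), np.repeat([0, 1], 4))
        assert st_["s2"].iloc[0] == 0
        assert st_["s2_post"].iloc[0] > 0

    def test_small_group_errors(self):
        lm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        with pytest.raises(DataError):
            fit_moderated_t(lm, [0, 1, 1])


class TestAdjustBH:
    def test_hand_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_stepup_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=37)
        assert adjust_bh(p) == pytest.approx(bh_stepup(p), abs=1e-12)

    def test_all_ones_and_singleton(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_order_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = adjust_bh(p)
        shuffled = adjust_bh([p[i] for i in perm])
        for pos, i in enumerate(perm):
            assert shuffled[pos] == pytest.approx(direct[i], abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            adjust_bh([0.5, 1.5])


class TestTopGenesAndIntersection:
    def _stats(self, p):
        return pd.DataFrame(
            {"pvalue": p, "adj_pvalue": adjust_bh(p)},
            index=[f"g{i}" for i in range(len(p))],
        )

    def test_alpha_one_returns_all_sorted(self):
        st_ = self._stats([0.5, 0.01, 0.2])
        assert top_genes(st_, alpha=1.0) == ["g1", "g2", "g0"]

    def test_alpha_zero_empty(self):
        assert top_genes(self._stats([0.1, 0.2]), alpha=0.0) == []

    def test_max_n_truncates(self):
        st_ = self._stats([0.001, 0.002, 0.003])
        assert top_genes(st_, alpha=1.0, max_n=2) == ["g0", "g1"]

    def test_intersection_ordered_by_first_list(self):
        assert intersect_gene_lists(["A", "B", "C"], ["C", "B", "D"]) == ["B", "C"]
        assert intersect_gene_lists(["A"], ["B"]) == []


class TestRecovery:
    def test_planted_genes_recovered_across_studies(self):
        """FC=4, 25/group: planted genes survive intersection with high
        sensitivity and low false-discovery proportion."""
        genes = TwoStudyDesign(n_genes=2000).gene_ids()
        de = frozenset(genes[:20])
        d = TwoStudyDesign(
            n_genes=2000, n_samples_per_group=((25, 25), (25, 25)),
            de_gene_ids=de, log2_fold_change=4.0, seed=17,
        )
        a, b, truth = simulate_two_study_counts(d)
        lists = []
        for cm in (a, b):
            f = filter_low_counts(cm, 0.5, 2)
            st_ = fit_moderated_t(log_cpm(f, 0.5), f.condition.to_numpy())
            lists.append(top_genes(st_, alpha=0.05))
        shared = intersect_gene_lists(lists[0], lists[1])
        tp = len(set(shared) & truth)
        assert tp / len(truth) >= 0.9
        fdp = (len(shared) - tp) / max(len(shared), 1)
        assert fdp <= 0.1


class TestSelectorEstimator:
    def test_fit_transform_selects_planted_genes(self):
        d = TwoStudyDesign(
            n_genes=500, n_samples_per_group=((25, 25), (25, 25)),
            de_gene_ids=frozenset(TwoStudyDesign(n_genes=500).gene_ids()[:5]),
            log2_fold_change=4.0, seed=2,
        )
        a, _, truth = simulate_two_study_counts(d)
        X = a.counts.T  # samples x genes
        sel = ModeratedTSelector(alpha=0.01).fit(X, a.condition.to_numpy())
        kept = set(sel.selected_genes_)
        assert truth <= kept
        assert sel.transform(X).shape == (50, len(kept))
        assert sel.get_support().sum() == len(kept)
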