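import itertools

import numpy as np
import pytest
from scipy import stats

from arraybench.gene_selection import (GENE_COUNT_GRID, RankedPairs,
                                       bonferroni_threshold,
                                       expand_pairs_to_genes,
                                       paired_distance_rank, relief_rank,
                                       select_genes, ttest_rank)


def welch_p(a, b):
    """Independent brute-force Welch p-value from the closed-form statistic."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestTtestRank:
    def test_strongly_shifted_gene_ranked_first(self):
        X = np.array([
            [0.1, 0.0, -0.1, 0.05, 3.0, 3.1, 2.9, 3.05],   # separated
            [0.3, -0.2, 0.1, 0.0, -0.1, 0.2, 0.05, -0.3],  # noise
        ])
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert ttest_rank(X, y).order[0] == 0

    def test_identical_class_values_rank_last(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 8))
        X[2] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # same values in both classes
        y = np.array(["a"] * 4 + ["b"] * 4)
        ranked = ttest_rank(X, y)
        assert ranked.order[-1] == 2
        assert ranked.scores[-1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 14))
        y = np.array(["a"] * 6 + ["b"] * 8)
        ranked = ttest_rank(X, y)
        oracle_p = np.array([welch_p(x[:6], x[6:]) for x in X])
        np.testing.assert_allclose(ranked.scores, np.sort(oracle_p), rtol=1e-9)
        np.testing.assert_array_equal(ranked.order, np.argsort(oracle_p))

    def test_small_class_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError):
            ttest_rank(X, np.array(["a", "b", "b", "b"]))


class TestBonferroni:
    def test_single_gene_is_alpha(self):
        assert bonferroni_threshold(1) == 0.05

    def test_scales_inversely_with_gene_count(self):
        assert bonferroni_threshold(500) == pytest.approx(1e-4)
        assert bonferroni_threshold(50, alpha=0.01) == pytest.approx(2e-4)


class TestReliefRank:
    def test_hand_enumerated_single_gene_weight(self):
        # class a = {0, 0.1}, class b = {1, 1.1}; range 1.1, m = 4:
        # per-observation (miss - hit) diffs: .9, .8, .8, .9 over range
        X = np.array([[0.0, 0.1, 1.0, 1.1]])
        y = np.array(["a", "a", "b", "b"])
        ranked = relief_rank(X, y)
        assert ranked.scores[0] == pytest.approx(3.4 / 4.4)

    def test_constant_gene_gets_zero_weight(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 10))
        X[1] = 5.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        ranked = relief_rank(X, y)
        w = ranked.scores[list(ranked.order).index(1)]
        assert w == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 12))
        y = np.array(["a"] * 6 + ["b"] * 6)
        r1, r2 = relief_rank(X, y), relief_rank(X, y)
        np.testing.assert_array_equal(r1.order, r2.order)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_separating_gene_outranks_noise(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 16))
        X[7, 8:] += 4.0
        y = np.array(["a"] * 8 + ["b"] * 8)
        assert relief_rank(X, y).order[0] == 7

    def test_singleton_class_skips_hit_term(self):
        X = np.array([[0.0, 0.2, 1.0, 1.1, 0.9]])
        y = np.array(["a", "a", "a", "a", "b"])
        ranked = relief_rank(X, y)  # must not raise
        assert np.isfinite(ranked.scores).all()


class TestPairedDistance:
    def test_three_four_five_triangle(self):
        # deltas (class-median differences) of 3 and 4 give distance 5
        X = np.array([
            [0.0, 0.0, 0.0, 3.0, 3.0, 3.0],
            [0.0, 0.0, 0.0, 4.0, 4.0, 4.0],
        ])
        y = np.array(["a"] * 3 + ["b"] * 3)
        ranked = paired_distance_rank(X, y)
        assert ranked.distances[0] == pytest.approx(5.0)

    def test_zero_delta_gene_degenerates_to_partner(self):
        X = np.array([
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],   # equal class medians
            [0.0, 0.1, -0.1, 2.0, 2.1, 1.9],  # delta = -2
        ])
        y = np.array(["a"] * 3 + ["b"] * 3)
        ranked = paired_distance_rank(X, y)
        assert ranked.distances[0] == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 12))
        y = np.array(["a"] * 6 + ["b"] * 6)
        ranked = paired_distance_rank(X, y)
        delta = np.median(X[:, :6], axis=1) - np.median(X[:, 6:], axis=1)
        brute = sorted(
            ((np.hypot(delta[i], delta[j]), i, j)
             for i, j in itertools.combinations(range(10), 2)),
            key=lambda t: (-t[0], t[1], t[2]))
        assert len(ranked.pairs) == 45
        for (d, i, j), pair, dist in zip(brute, ranked.pairs, ranked.distances):
            assert (i, j) == tuple(pair)
            assert d == pytest.approx(dist)

    def test_top_pair_is_two_largest_deltas(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 10))
        y = np.array(["a"] * 5 + ["b"] * 5)
        ranked = paired_distance_rank(X, y)
        adelta = np.abs(ranked.delta)
        top2 = set(np.argsort(-adelta)[:2])
        assert set(ranked.pairs[0]) == top2

    def test_candidate_cap_restricts_to_variance_or_mean_leaders(self):
        rng = np.random.default_rng(7)
        X = rng.normal(scale=0.1, size=(50, 10))
        X[3] *= 40.0          # variance leader
        X[8] += 5.0           # |mean| leader
        y = np.array(["a"] * 5 + ["b"] * 5)
        ranked = paired_distance_rank(X, y, n_top=1)
        assert set(np.unique(ranked.pairs)) == {3, 8}


class TestExpandPairs:
    @staticmethod
    def make_ranked(pairs, delta):
        delta = np.asarray(delta, dtype=float)
        pairs = np.asarray(pairs)
        d = np.hypot(delta[pairs[:, 0]], delta[pairs[:, 1]])
        return RankedPairs(pairs=pairs, distances=d, delta=delta)

    def test_walk_of_stated_rule(self):
        # pairs [(a,b), (a,c), (d,e)] with a=0, b=1, c=2, d=3, e=4
        ranked = self.make_ranked([(0, 1), (0, 2), (3, 4)],
                                  [5.0, 4.0, 3.0, 2.0, 1.0])
        np.testing.assert_array_equal(expand_pairs_to_genes(ranked, 3),
                                      [0, 1, 2])

    def test_n2_returns_top_pair_larger_delta_first(self):
        ranked = self.make_ranked([(0, 1)], [2.0, 6.0])
        np.testing.assert_array_equal(expand_pairs_to_genes(ranked, 2), [1, 0])

    def test_overflow_takes_larger_delta_gene(self):
        ranked = self.make_ranked([(0, 1), (2, 3)], [5.0, 4.0, 1.0, 3.0])
        np.testing.assert_array_equal(expand_pairs_to_genes(ranked, 3),
                                      [0, 1, 3])

    def test_exhausted_pairs_warn(self):
        ranked = self.make_ranked([(0, 1)], [1.0, 2.0])
        with pytest.warns(UserWarning):
            out = expand_pairs_to_genes(ranked, 5)
        assert set(out) == {0, 1}


class TestSelectGenes:
    def test_planted_genes_selected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(scale=0.1, size=(50, 20))
        X[4, 10:] += 10.0
        X[17, 10:] -= 10.0
        y = np.array(["a"] * 10 + ["b"] * 10)
        assert set(select_genes("ttest", X, y, 2)) == {4, 17}

    @pytest.mark.parametrize("method", ["ttest", "relief", "paired_distance"])
    def test_full_selection_is_permutation(self, method):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 10))
        y = np.array(["a"] * 5 + ["b"] * 5)
        out = select_genes(method, X, y, 12)
        assert sorted(out) == list(range(12))

    def test_off_grid_count_rejected(self):
        X = np.zeros((30, 10))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            select_genes("ttest", X, y, 17)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            select_genes("variance", np.zeros((4, 4)),
                         np.array(["a", "a", "b", "b"]), 2)

    def test_grid_has_21_counts(self):
        assert len(GENE_COUNT_GRID) == 21
        assert GENE_COUNT_GRID[0] == 2 and GENE_COUNT_GRID[-1] == 1000
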