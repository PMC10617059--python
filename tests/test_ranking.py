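import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snfs.dataset import ExpressionDataset
from snfs.ranking import (
    RankedFeatureList,
    chi_square_scores,
    discretize,
    info_gain_scores,
    merge_ranks,
    rf_importance_scores,
    select_candidates,
    svm_sqrt_rfe_ranking,
)


def _two_class(values, labels):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionDataset(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        labels,
    )


# The 2x2 contingency table [[10, 5], [5, 10]]: chi-square = 10/3 and
# information gain = 1 - H(1/3) by direct computation.
TABLE_GENE = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
TABLE_LABELS = ["a"] * 15 + ["b"] * 15


class TestDiscretize:
    def test_equal_frequency_split(self):
        assert list(discretize([1, 2, 3, 4], n_bins=2)) == [0, 0, 1, 1]

    def test_constant_gene_single_category(self):
        assert len(set(discretize([5.0] * 10, n_bins=4))) == 1

    def test_permutation_invariance_with_ties(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 4, size=40).astype(float)  # heavy ties
        codes = discretize(v, n_bins=3)
        perm = rng.permutation(40)
        codes_perm = discretize(v[perm], n_bins=3)
        np.testing.assert_array_equal(codes_perm, codes[perm])

    def test_matrix_matches_per_gene(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 30))
        mat = discretize(x, n_bins=4)
        for i in range(5):
            np.testing.assert_array_equal(mat[i], discretize(x[i], n_bins=4))

    def test_rejects_single_bin(self):
        with pytest.raises(ValueError):
            discretize([1.0, 2.0], n_bins=1)


class TestChiSquare:
    def test_perfect_two_by_two_equals_n(self):
        data = _two_class([0] * 10 + [1] * 10, ["a"] * 10 + ["b"] * 10)
        rl = chi_square_scores(data, n_bins=2)
        assert rl.scores[0] == pytest.approx(20.0)

    def test_independent_gene_scores_zero(self):
        data = _two_class([0, 1] * 10, (["a", "a", "b", "b"] * 5))
        assert chi_square_scores(data, n_bins=2).scores.max() == pytest.approx(0.0)

    def test_hand_computed_table(self):
        rl = chi_square_scores(_two_class(TABLE_GENE, TABLE_LABELS), n_bins=2)
        assert rl.scores[0] == pytest.approx(10 / 3)

    def test_constant_gene_scores_zero(self):
        data = _two_class([[3.0] * 20, [0] * 10 + [1] * 10],
                          ["a"] * 10 + ["b"] * 10)
        scores = dict(zip(chi_square_scores(data, 2).gene_ids,
                          chi_square_scores(data, 2).scores))
        assert scores["g0"] == 0.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(20, 60))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        data = _two_class(values, labels)
        rl = chi_square_scores(data, n_bins=4)
        scores = dict(zip(rl.gene_ids, rl.scores))
        codes = discretize(values, n_bins=4)
        for i in range(20):
            table = np.array([np.bincount(codes[i, labels == c], minlength=4)
                              for c in ("a", "b")]).T
            table = table[table.sum(axis=1) > 0]
            expected = stats.chi2_contingency(table, correction=False).statistic
            assert scores[f"g{i}"] == pytest.approx(expected)


class TestInfoGain:
    def test_perfect_separator_one_bit(self):
        data = _two_class([0] * 10 + [1] * 10, ["a"] * 10 + ["b"] * 10)
        assert info_gain_scores(data, 2).scores[0] == pytest.approx(1.0)

    def test_independent_gene_zero_bits(self):
        data = _two_class([0, 1] * 10, (["a", "a", "b", "b"] * 5))
        assert info_gain_scores(data, 2).scores.max() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        rl = info_gain_scores(_two_class(TABLE_GENE, TABLE_LABELS), n_bins=2)
        h = -(1 / 3) * np.log2(1 / 3) - (2 / 3) * np.log2(2 / 3)
        assert rl.scores[0] == pytest.approx(1 - h, abs=1e-12)


class TestRandomForest:
    def test_informative_gene_ranked_first(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 200))
        labels = np.array(["a"] * 100 + ["b"] * 100)
        values[17, labels == "b"] += 3.0  # 3-SD effect
        rl = rf_importance_scores(_two_class(values, labels), n_trees=100, seed=1)
        assert rl.gene_ids[0] == "g17"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        data = _two_class(rng.normal(size=(15, 40)), ["a"] * 20 + ["b"] * 20)
        a = rf_importance_scores(data, n_trees=50, seed=9)
        b = rf_importance_scores(data, n_trees=50, seed=9)
        np.testing.assert_array_equal(a.gene_ids, b.gene_ids)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestSvmSqrtRfe:
    def test_informative_gene_outranks_constant(self):
        values = np.zeros((2, 20))
        values[0] = [-1] * 10 + [1] * 10
        rl = svm_sqrt_rfe_ranking(_two_class(values, ["a"] * 10 + ["b"] * 10))
        assert list(rl.gene_ids) == ["g0", "g1"]

    def test_full_permutation_and_determinism(self):
        rng = np.random.default_rng(8)
        data = _two_class(rng.normal(size=(40, 30)), ["a"] * 15 + ["b"] * 15)
        a = svm_sqrt_rfe_ranking(data)
        b = svm_sqrt_rfe_ranking(data)
        assert sorted(a.gene_ids) == sorted(data.gene_ids)
        np.testing.assert_array_equal(a.gene_ids, b.gene_ids)

    def test_recovers_planted_signal(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(60, 80))
        labels = np.array(["a"] * 40 + ["b"] * 40)
        for g in (5, 23, 41):
            values[g, labels == "b"] += 2.5
        rl = svm_sqrt_rfe_ranking(_two_class(values, labels))
        assert {"g5", "g23", "g41"} <= set(rl.gene_ids[:6])


class TestMergeAndSelect:
    def _rl(self, method, genes, higher=True):
        scores = np.arange(len(genes), 0, -1, dtype=float)
        return RankedFeatureList(method, np.array(genes), scores, higher)

    def test_two_list_example(self):
        # X ranks (1, 3), Y ranks (2, 1), Z ranks (3, 2)
        a = self._rl("m1", ["X", "Y", "Z"])
        b = self._rl("m2", ["Y", "Z", "X"])
        merged = merge_ranks([a, b])
        assert list(merged.gene_ids[:2]) == ["Y", "X"]
        assert merged.scores[0] == pytest.approx(1.5)
        assert merged.scores[1] == pytest.approx(2.0)

    def test_idempotent_on_identical_lists(self):
        a = self._rl("m1", ["A", "B", "C", "D"])
        merged = merge_ranks([a, self._rl("m2", ["A", "B", "C", "D"])])
        assert list(merged.gene_ids) == ["A", "B", "C", "D"]

    def test_three_lists_match_brute_force(self):
        rng = np.random.default_rng(2)
        genes = np.array(["a", "b", "c", "d", "e"])
        lists = [self._rl(f"m{i}", rng.permutation(genes)) for i in range(3)]
        merged = merge_ranks(lists)
        pos = {g: np.mean([list(rl.gene_ids).index(g) + 1 for rl in lists])
               for g in genes}
        expected = sorted(genes, key=lambda g: (pos[g], g))
        assert list(merged.gene_ids) == expected

    def test_symmetric_in_arguments(self):
        a = self._rl("m1", ["A", "C", "B"])
        b = self._rl("m2", ["B", "A", "C"])
        assert list(merge_ranks([a, b]).gene_ids) == list(merge_ranks([b, a]).gene_ids)

    def test_mismatched_gene_sets_rejected(self):
        a = self._rl("m1", ["A", "B"])
        b = self._rl("m2", ["A", "C"])
        with pytest.raises(ValueError, match="[BC]"):
            merge_ranks([a, b])

    @pytest.mark.parametrize("p,percent,expected", [(7129, 0.01, 72),
                                                    (10_000, 0.05, 500)])
    def test_candidate_count_uses_ceiling(self, p, percent, expected):
        genes = np.array([f"g{i:05d}" for i in range(p)])
        rl = RankedFeatureList("m", genes, np.arange(p, dtype=float)[::-1])
        assert len(select_candidates(rl, percent)) == expected

    def test_percent_one_keeps_order(self):
        rl = self._rl("m", ["A", "B", "C"])
        assert list(select_candidates(rl, 1.0).gene_ids) == ["A", "B", "C"]

    def test_percent_out_of_range(self):
        rl = self._rl("m", ["A", "B"])
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_candidates(rl, bad)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=40),
       st.integers(2, 8))
def test_discretize_codes_bounded_by_bin_count(values, n_bins):
    codes = discretize(values, n_bins)
    assert codes.min() >= 0 and codes.max() < n_bins


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.permutations(list("ABCDEFG")), st.permutations(list("ABCDEFG")))
def test_merge_ranks_symmetric_for_any_orderings(p1, p2):
    scores = np.arange(7, 0, -1, dtype=float)
    a = RankedFeatureList("m1", np.array(p1), scores)
    b = RankedFeatureList("m2", np.array(p2), scores)
    ab = merge_ranks([a, b])
    ba = merge_ranks([b, a])
    assert list(ab.gene_ids) == list(ba.gene_ids)
    np.testing.assert_allclose(ab.scores, ba.scores)


class TestRankingInvariants:
    def test_all_methods_return_permutations(self, small_sim):
        train, _ = small_sim
        sub = train.subset(train.gene_ids[:80])
        for rl in (chi_square_scores(sub), info_gain_scores(sub),
                   rf_importance_scores(sub, 50, seed=2), svm_sqrt_rfe_ranking(sub)):
            assert sorted(rl.gene_ids) == sorted(sub.gene_ids)

    def test_scores_ordered_best_to_worst(self, small_sim):
        train, _ = small_sim
        sub = train.subset(train.gene_ids[:60])
        rl = chi_square_scores(sub)
        assert (np.diff(rl.scores) <= 1e-12).all()
        rfe = svm_sqrt_rfe_ranking(sub)
        assert (np.diff(rfe.scores) >= 0).all() and not rfe.higher_is_better
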