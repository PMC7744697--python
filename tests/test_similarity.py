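import numpy as np
import pytest

from idsim.similarity import (
    DISTANCE,
    SIMILARITY,
    build_pair_index,
    orient,
    pattern_distance,
    pattern_similarity,
    permute_similarity,
    rating_profile_similarity,
    univariate_similarity,
)


class TestPairIndex:
    def test_two_subjects_single_pair(self):
        idx = build_pair_index(["a", "b"])
        np.testing.assert_array_equal(idx.pairs, [[0, 1]])

    def test_four_subjects_lexicographic(self):
        idx = build_pair_index([1, 2, 3, 4])
        expected = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        assert [tuple(p) for p in idx.pairs] == expected

    def test_study_size_pair_count(self):
        idx = build_pair_index([f"S{i}" for i in range(28)])
        assert idx.n_pairs == 378

    def test_each_subject_in_n_minus_1_pairs(self):
        idx = build_pair_index(list("abcdefg"))
        counts = np.bincount(idx.pairs.ravel())
        assert (counts == 6).all()

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_pair_index(["only"])


class TestPatternDistance:
    def test_identical_patterns(self):
        assert pattern_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_three_four_five(self):
        assert pattern_distance([0, 0, 0], [3, 4, 0]) == 5.0

    def test_matches_elementwise_loop(self, rng):
        a, b = rng.normal(size=25), rng.normal(size=25)
        oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert pattern_distance(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pattern_distance([1, 2], [1, 2, 3])

    def test_pairwise_matrix_matches_scalar(self, rng):
        pats = rng.normal(size=(5, 25))
        idx = build_pair_index(list("abcde"))
        vec = pattern_similarity(pats, idx, "roi")
        for (i, j), v in zip(idx.pairs, vec.values):
            assert v == pytest.approx(pattern_distance(pats[i], pats[j]))


class TestUnivariateSimilarity:
    def test_constant_scores(self):
        idx = build_pair_index(list("abc"))
        np.testing.assert_array_equal(univariate_similarity([1, 1, 1], idx, "x").values, [0, 0, 0])

    def test_two_subjects(self):
        idx = build_pair_index(list("ab"))
        np.testing.assert_array_equal(univariate_similarity([1, 4], idx, "x").values, [3])

    def test_three_subjects_enumerated(self):
        idx = build_pair_index(list("abc"))
        np.testing.assert_array_equal(univariate_similarity([2, 5, 1], idx, "x").values, [3, 1, 4])

    def test_missing_score_rejected(self):
        idx = build_pair_index(list("ab"))
        with pytest.raises(ValueError, match="missing"):
            univariate_similarity([1.0, np.nan], idx, "x")

    def test_positive_scaling_scales_vector(self, rng):
        idx = build_pair_index(list("abcdef"))
        scores = rng.normal(size=6)
        base = univariate_similarity(scores, idx, "x").values
        scaled = univariate_similarity(3.5 * scores, idx, "x").values
        np.testing.assert_allclose(scaled, 3.5 * base)


class TestRatingProfileSimilarity:
    def test_identical_profiles(self):
        idx = build_pair_index(list("ab"))
        mat = np.array([[1, 2, 3, 4], [1, 2, 3, 4.0]])
        r, dmean, dsd = rating_profile_similarity(mat, idx, "pMSV")
        assert r.values[0] == pytest.approx(1.0)
        assert dmean.values[0] == 0.0
        assert dsd.values[0] == 0.0

    def test_affine_profiles_correlate_perfectly(self):
        idx = build_pair_index(list("ab"))
        a = np.array([1, 2.0, 4, 3])
        mat = np.vstack([a, 2 + 3 * a])
        r, dmean, dsd = rating_profile_similarity(mat, idx, "pMSV")
        assert r.values[0] == pytest.approx(1.0)
        assert dmean.values[0] > 0 and dsd.values[0] > 0

    def test_pearson_matches_product_moment_formula(self):
        idx = build_pair_index(list("ab"))
        a = np.array([1.0, 3.0, 2.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 4.0])
        r, dmean, dsd = rating_profile_similarity(np.vstack([a, b]), idx, "pAS")
        za, zb = a - a.mean(), b - b.mean()
        oracle = np.sum(za * zb) / np.sqrt(np.sum(za**2) * np.sum(zb**2))
        assert r.values[0] == pytest.approx(oracle, rel=1e-12)
        assert dmean.values[0] == pytest.approx(abs(a.mean() - b.mean()))
        assert dsd.values[0] == pytest.approx(abs(a.std(ddof=1) - b.std(ddof=1)))

    def test_zero_variance_profile_names_subject(self):
        idx = build_pair_index(["S01", "S02"])
        mat = np.array([[2, 2, 2, 2.0], [1, 2, 3, 4.0]])
        with pytest.raises(ValueError, match="S01"):
            rating_profile_similarity(mat, idx, "pMSV")


class TestOrient:
    def test_r_of_one_maps_to_zero(self):
        idx = build_pair_index(list("ab"))
        mat = np.array([[1, 2, 3, 4], [1, 2, 3, 4.0]])
        r, *_ = rating_profile_similarity(mat, idx, "x")
        assert orient(r).values[0] == pytest.approx(0.0)
        assert orient(r).orientation == DISTANCE

    def test_r_of_minus_one_maps_to_two(self):
        idx = build_pair_index(list("ab"))
        a = np.array([1.0, 2, 3, 4])
        r, *_ = rating_profile_similarity(np.vstack([a, -a]), idx, "x")
        assert r.orientation == SIMILARITY
        assert orient(r).values[0] == pytest.approx(2.0)

    def test_distance_vectors_pass_through(self, rng):
        idx = build_pair_index(list("abcd"))
        vec = univariate_similarity(rng.normal(size=4), idx, "x")
        assert orient(vec) is vec

    def test_orientation_is_inert_for_unique_variance(self, rng):
        # refitting with r vs 1-r must give identical unique-variance credit
        from idsim.regression import RegressorGroup, round_robin

        idx = build_pair_index([f"S{i}" for i in range(10)])
        mats = rng.normal(size=(10, 6))
        r, dmean, dsd = rating_profile_similarity(mats, idx, "pMSV")
        other = univariate_similarity(rng.normal(size=10), idx, "MJ")
        y = univariate_similarity(rng.normal(size=10), idx, "y")
        for focal in (r, orient(r)):
            groups = [
                RegressorGroup("pMSV", (focal, dmean, dsd), "psa"),
                RegressorGroup("MJrisk", (other,), "intrinsic"),
            ]
            res = round_robin(groups, y, idx)
            if focal is r:
                baseline = res.delta_r2
            else:
                for g in baseline:
                    assert res.delta_r2[g] == pytest.approx(baseline[g], abs=1e-12)


class TestPermuteSimilarity:
    def test_identity_permutation_is_noop(self, rng):
        idx = build_pair_index(list("abcde"))
        vec = univariate_similarity(rng.normal(size=5), idx, "x")
        out = permute_similarity(vec, idx, np.arange(5))
        np.testing.assert_array_equal(out.values, vec.values)

    def test_equals_recomputation_from_permuted_scores(self, rng):
        idx = build_pair_index(list("abcdefg"))
        scores = rng.normal(size=7)
        vec = univariate_similarity(scores, idx, "x")
        perm = rng.permutation(7)
        via_matrix = permute_similarity(vec, idx, perm)
        direct = univariate_similarity(scores[perm], idx, "x")
        np.testing.assert_allclose(via_matrix.values, direct.values)

    def test_equals_recomputation_for_pattern_distance(self, rng):
        idx = build_pair_index(list("abcdef"))
        pats = rng.normal(size=(6, 25))
        vec = pattern_similarity(pats, idx, "roi")
        perm = rng.permutation(6)
        via_matrix = permute_similarity(vec, idx, perm)
        direct = pattern_similarity(pats[perm], idx, "roi")
        np.testing.assert_allclose(via_matrix.values, direct.values)

    def test_value_multiset_preserved(self, rng):
        idx = build_pair_index(list("abcde"))
        vec = univariate_similarity(rng.normal(size=5), idx, "x")
        out = permute_similarity(vec, idx, rng.permutation(5))
        np.testing.assert_allclose(np.sort(out.values), np.sort(vec.values))
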