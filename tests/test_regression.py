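import numpy as np
import pandas as pd
import pytest

from idsim.regression import (
    RegressorGroup,
    assemble_design,
    category_summary,
    fit_r2,
    round_robin,
    subject_intercepts,
    ProjectedDelta,
)
from idsim.roi_patterns import ROISpec
from idsim.similarity import SimilarityVector, build_pair_index, univariate_similarity


def normal_equations_r2(X, y):
    """Independent oracle: solve X'X b = X'y via pseudoinverse, R2 from SSE."""
    XtX = X.T @ X
    beta = np.linalg.pinv(XtX) @ (X.T @ y)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    return 1.0 - resid @ resid / sst


def make_vec(values, name="v"):
    return SimilarityVector(name=name, orientation="distance", values=np.asarray(values, float))


def random_groups(rng, idx, n_groups=3, max_members=2):
    groups = []
    for g in range(n_groups):
        members = tuple(
            make_vec(rng.normal(size=idx.n_pairs), name=f"g{g}m{m}")
            for m in range(rng.integers(1, max_members + 1))
        )
        groups.append(RegressorGroup(f"g{g}", members, "psa"))
    return groups


class TestAssembleDesign:
    def test_subject_intercept_coding_rule(self):
        idx = build_pair_index(list("abc"))
        Z = subject_intercepts(idx)
        np.testing.assert_array_equal(Z[0], [1, 1, 0])  # pair (1,2)
        np.testing.assert_array_equal(Z[1], [1, 0, 1])
        np.testing.assert_array_equal(Z[2], [0, 1, 1])

    def test_column_count(self, rng):
        idx = build_pair_index(list("abcde"))
        groups = random_groups(rng, idx, n_groups=2, max_members=2)
        design = assemble_design(groups, idx)
        n_members = sum(len(g.members) for g in groups)
        assert design.X.shape[1] == 1 + n_members + 5

    def test_each_subint_column_has_n_minus_1_ones(self):
        idx = build_pair_index([f"S{i}" for i in range(9)])
        Z = subject_intercepts(idx)
        np.testing.assert_array_equal(Z.sum(axis=0), np.full(9, 8))

    def test_constant_regressor_named_in_error(self):
        idx = build_pair_index(list("abc"))
        groups = [RegressorGroup("flat", (make_vec([2.0, 2.0, 2.0], name="flatvec"),), "psa")]
        with pytest.raises(ValueError, match="flatvec"):
            assemble_design(groups, idx)


class TestFitR2:
    def test_response_equal_to_regressor_gives_r2_one(self, rng):
        x = rng.normal(size=12)
        X = np.column_stack([np.ones(12), x])
        r2, _ = fit_r2(X, x)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_gives_r2_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # centered, orthogonal to x and const
        X = np.column_stack([np.ones(4), x])
        r2, _ = fit_r2(X, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_toy_instance(self, rng):
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        y = rng.normal(size=6)
        r2, _ = fit_r2(X, y)
        assert r2 == pytest.approx(normal_equations_r2(X, y), abs=1e-10)

    def test_matches_statsmodels_on_full_rank_instance(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
        y = rng.normal(size=30)
        r2, _ = fit_r2(X, y)
        assert r2 == pytest.approx(sm.OLS(y, X).fit().rsquared, abs=1e-10)

    def test_rank_deficiency_is_inert(self, rng):
        # duplicating a column must not change R2 (column space unchanged)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        X1 = np.column_stack([np.ones(15), x])
        X2 = np.column_stack([np.ones(15), x, x])
        assert fit_r2(X1, y)[0] == pytest.approx(fit_r2(X2, y)[0], abs=1e-12)


class TestRoundRobin:
    def test_orthogonal_regressors_partition_cleanly(self):
        idx = build_pair_index(list("abcd"))  # 6 pairs
        x1 = np.array([1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -2.0, 0.0, -1.0, 1.0])
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # orthogonalize; both are centered
        y = 2 * x1 + np.array([0.1, -0.2, 0.3, -0.1, -0.05, -0.05])
        groups = [
            RegressorGroup("g1", (make_vec(x1, "x1"),), "psa"),
            RegressorGroup("g2", (make_vec(x2, "x2"),), "psa"),
        ]
        res = round_robin(groups, make_vec(y, "y"), idx, include_subints=False)
        alone1 = fit_r2(np.column_stack([np.ones(6), x1]), y)[0]
        assert res.delta_r2["g1"] == pytest.approx(alone1, abs=1e-10)
        assert res.shared == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_vector_credits_nothing_uniquely(self, rng):
        idx = build_pair_index(list("abcde"))
        x = make_vec(rng.normal(size=10), "x")
        y = make_vec(x.values + 0.1 * rng.normal(size=10), "y")
        groups = [
            RegressorGroup("g1", (x,), "psa"),
            RegressorGroup("g2", (make_vec(x.values, "x_copy"),), "psa"),
        ]
        res = round_robin(groups, y, idx, include_subints=False)
        assert res.delta_r2["g1"] == pytest.approx(0.0, abs=1e-12)
        assert res.delta_r2["g2"] == pytest.approx(0.0, abs=1e-12)
        assert res.shared == pytest.approx(res.r2_full, abs=1e-12)

    def test_single_group_gets_full_r2(self, rng):
        idx = build_pair_index(list("abcde"))
        x = make_vec(rng.normal(size=10), "x")
        y = make_vec(rng.normal(size=10), "y")
        res = round_robin([RegressorGroup("only", (x,), "psa")], y, idx, include_subints=False)
        assert res.delta_r2["only"] == pytest.approx(res.r2_full, abs=1e-12)
        assert res.shared == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        idx = build_pair_index([f"S{i}" for i in range(8)])
        groups = random_groups(rng, idx)
        y = make_vec(rng.normal(size=idx.n_pairs), "y")
        res = round_robin(groups, y, idx)
        assert all(d >= 0 for d in res.delta_r2.values())
        total = sum(res.delta_r2.values()) + res.shared
        assert total == pytest.approx(res.r2_full, abs=1e-10)
        assert 0 <= res.r2_full <= 1

    def test_affine_transform_of_regressor_is_inert(self, rng):
        idx = build_pair_index([f"S{i}" for i in range(8)])
        groups = random_groups(rng, idx)
        y = make_vec(rng.normal(size=idx.n_pairs), "y")
        base = round_robin(groups, y, idx)
        v0 = groups[0].members[0]
        shifted = make_vec(3.0 - 2.0 * v0.values, v0.name)
        groups2 = [RegressorGroup("g0", (shifted,) + groups[0].members[1:], "psa")] + groups[1:]
        res = round_robin(groups2, y, idx)
        for g in base.delta_r2:
            key = g if g in res.delta_r2 else "g0"
            assert res.delta_r2[key] == pytest.approx(base.delta_r2[g], abs=1e-10)

    def test_projected_delta_agrees_with_refit(self, rng):
        # the fast path used in resampling must equal the two-model refit
        idx = build_pair_index([f"S{i}" for i in range(10)])
        groups = random_groups(rng, idx, n_groups=3)
        y = make_vec(rng.normal(size=idx.n_pairs), "y")
        res = round_robin(groups, y, idx)
        design = assemble_design(groups, idx)
        cols = np.asarray(design.column_groups)
        for g in groups:
            proj = ProjectedDelta(design.X[:, cols != g.name], y.values)
            Z = np.column_stack([m.values for m in g.members])
            assert proj.delta_r2(Z) == pytest.approx(res.delta_r2[g.name], abs=1e-10)


class TestCategorySummary:
    def make_result(self, roi_id, deltas, shared=0.0):
        from idsim.regression import RoundRobinResult

        return RoundRobinResult(roi_id=roi_id, r2_full=sum(deltas.values()) + shared, delta_r2=deltas, shared=shared)

    CATS = {"wbFxnSim": "neural", "MJrisk": "intrinsic", "pMSV": "psa", "subints": "unexplained"}

    def test_single_roi_per_source_echoes_sums(self):
        specs = [ROISpec(1, "a_priori", (0, 0, 0)), ROISpec(2, "exploratory", (0, 0, 0))]
        results = {
            1: self.make_result(1, {"wbFxnSim": 0.2, "MJrisk": 0.05, "pMSV": 0.1, "subints": 0.3}, shared=0.1),
            2: self.make_result(2, {"wbFxnSim": 0.1, "MJrisk": 0.0, "pMSV": 0.2, "subints": 0.25}, shared=0.0),
        }
        out = category_summary(results, specs, categories=self.CATS)
        assert out.loc["a_priori", "neural"] == pytest.approx(0.2)
        assert out.loc["a_priori", "psa"] == pytest.approx(0.1)
        assert out.loc["exploratory", "unexplained"] == pytest.approx(0.25)

    def test_all_zero_deltas_give_zero_means(self):
        specs = [ROISpec(1, "confirmatory", (0, 0, 0))]
        results = {1: self.make_result(1, {"wbFxnSim": 0.0, "MJrisk": 0.0, "pMSV": 0.0, "subints": 0.0})}
        out = category_summary(results, specs, categories=self.CATS)
        assert (out[["neural", "intrinsic", "psa", "unexplained"]].to_numpy() == 0).all()

    def test_two_roi_means_match_hand_arithmetic(self):
        specs = [ROISpec(1, "a_priori", (0, 0, 0)), ROISpec(2, "a_priori", (0, 0, 0))]
        results = {
            1: self.make_result(1, {"wbFxnSim": 0.2, "MJrisk": 0.0, "pMSV": 0.1, "subints": 0.1}),
            2: self.make_result(2, {"wbFxnSim": 0.4, "MJrisk": 0.1, "pMSV": 0.3, "subints": 0.2}),
        }
        out = category_summary(results, specs, categories=self.CATS)
        assert out.loc["a_priori", "neural"] == pytest.approx(0.3)
        assert out.loc["a_priori", "intrinsic"] == pytest.approx(0.05)
        assert out.loc["a_priori", "psa"] == pytest.approx(0.2)

    def test_missing_roi_result_raises(self):
        specs = [ROISpec(1, "a_priori", (0, 0, 0)), ROISpec(2, "a_priori", (0, 0, 0))]
        results = {1: self.make_result(1, {"wbFxnSim": 0.2, "subints": 0.1})}
        with pytest.raises(ValueError, match="ROI 2"):
            category_summary(results, specs, categories=self.CATS)
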