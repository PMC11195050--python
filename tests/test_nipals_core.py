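import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbnipals import (
    DecompositionConfig,
    DecompositionResult,
    PreprocessConfig,
    SyntheticSpec,
    apply_preprocessor,
    block_contributions,
    concatenate_global,
    decompose,
    deflate,
    generate,
    objective_value,
    solve_order,
    top_features,
    variance_explained,
)
from mbnipals.nipals_core import NoSignalError

from .conftest import centered_blocks, make_dataset


def direct_objective(blocks, loadings, w):
    """Independent scalar evaluation of the maximized quantity."""
    n = blocks[0].shape[0]
    f = np.zeros(n)
    for wk, X, a in zip(w, blocks, loadings):
        f = f + wk * (X @ a)
    total = 0.0
    for X, a in zip(blocks, loadings):
        total += (np.dot(X @ a, f) / (n - 1)) ** 2
    return total


def unit(v):
    return v / np.linalg.norm(v)


class TestObjectiveValue:
    def test_zero_blocks_give_zero(self):
        blocks = [np.zeros((6, 3)), np.zeros((6, 2))]
        loadings = [unit(np.ones(3)), unit(np.ones(2))]
        w = unit(np.ones(2))
        assert objective_value(blocks, loadings, w) == 0.0

    def test_single_block_identity(self, rng):
        X = centered_blocks(rng, 7, [4])[0]
        a = unit(rng.standard_normal(4))
        val = objective_value([X], [a], np.array([1.0]))
        expected = (np.linalg.norm(X @ a) ** 2 / 6) ** 2
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_evaluation(self, rng):
        blocks = centered_blocks(rng, 6, [3, 2])
        loadings = [unit(rng.standard_normal(3)), unit(rng.standard_normal(2))]
        w = unit(rng.standard_normal(2))
        assert objective_value(blocks, loadings, w) == pytest.approx(
            direct_objective(blocks, loadings, w), rel=1e-12
        )

    def test_non_unit_inputs_rejected(self, rng):
        blocks = centered_blocks(rng, 6, [3])
        with pytest.raises(ValueError, match="unit-norm"):
            objective_value(blocks, [np.full(3, 0.9)], np.array([1.0]))
        with pytest.raises(ValueError, match="unit-norm"):
            objective_value(blocks, [unit(np.ones(3))], np.array([2.0]))


class TestSolveOrder:
    def test_single_block_svd_oracle(self, rng):
        X = centered_blocks(rng, 8, [5])[0]
        sol = solve_order([X], DecompositionConfig(num_factors=1, tol=1e-13))
        _, s, Vt = np.linalg.svd(X)
        a = Vt[0] if Vt[0] @ sol.block_loadings[0] > 0 else -Vt[0]
        assert np.linalg.norm(sol.block_loadings[0] - a) < 1e-6
        assert np.linalg.norm(sol.global_score - X @ a) < 1e-6 * s[0]
        assert sol.eigenvalue == pytest.approx((s[0] ** 2 / 7) ** 2, rel=1e-9)

    def test_two_identical_blocks_symmetric_weights(self, rng):
        X = centered_blocks(rng, 9, [4])[0]
        sol = solve_order([X, X.copy()], DecompositionConfig(num_factors=1, tol=1e-13))
        np.testing.assert_allclose(sol.block_weights, [2**-0.5, 2**-0.5], atol=1e-8)
        np.testing.assert_allclose(
            sol.block_loadings[0], sol.block_loadings[1], atol=1e-10
        )

    def test_tolerance_stability(self, rng):
        blocks = centered_blocks(rng, 10, [6, 4])
        loose = solve_order(
            [b.copy() for b in blocks], DecompositionConfig(num_factors=1, tol=1e-9)
        )
        tight = solve_order(
            [b.copy() for b in blocks], DecompositionConfig(num_factors=1, tol=1e-12)
        )
        for a1, a2 in zip(loose.block_loadings, tight.block_loadings):
            assert np.linalg.norm(a1 - a2) < 1e-6

    def test_global_score_is_weighted_sum(self, rng):
        blocks = centered_blocks(rng, 8, [3, 5, 2])
        sol = solve_order(blocks, DecompositionConfig(num_factors=1))
        recon = sum(
            w * f for w, f in zip(sol.block_weights, sol.block_scores)
        )
        np.testing.assert_allclose(sol.global_score, recon, atol=1e-10)

    def test_unit_norm_constraints(self, rng):
        blocks = centered_blocks(rng, 12, [5, 7])
        sol = solve_order(blocks, DecompositionConfig(num_factors=1))
        assert np.linalg.norm(sol.block_weights) == pytest.approx(1.0, abs=1e-10)
        for a in sol.block_loadings:
            assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-10)

    def test_objective_trace_matches_objective_value(self, rng):
        blocks = centered_blocks(rng, 8, [4, 3])
        sol = solve_order(blocks, DecompositionConfig(num_factors=1, tol=1e-13))
        assert sol.objective_trace[-1] == pytest.approx(
            objective_value(blocks, sol.block_loadings, sol.block_weights), rel=1e-9
        )

    def test_degenerate_block_weight_pinned_to_zero(self, rng):
        blocks = [centered_blocks(rng, 8, [4])[0], np.zeros((8, 3))]
        sol = solve_order(blocks, DecompositionConfig(num_factors=1))
        assert sol.degenerate_blocks == [1]
        assert sol.block_weights[1] == 0.0
        assert abs(sol.block_weights[0]) == pytest.approx(1.0, abs=1e-12)

    def test_all_degenerate_rejected(self):
        with pytest.raises(NoSignalError, match="no remaining signal"):
            solve_order([np.zeros((5, 2)), np.zeros((5, 4))], DecompositionConfig())

    def test_sign_convention(self, rng):
        blocks = centered_blocks(rng, 10, [4, 6])
        sol = solve_order(blocks, DecompositionConfig(num_factors=1))
        gl = np.concatenate(
            [w * a for w, a in zip(sol.block_weights, sol.block_loadings)]
        )
        assert gl[np.argmax(np.abs(gl))] > 0


class TestDeflate:
    def test_block_deflation_annihilates_loading(self, rng):
        blocks = centered_blocks(rng, 9, [5, 3])
        sol = solve_order([b.copy() for b in blocks], DecompositionConfig())
        deflated = deflate(blocks, sol, "block")
        for X, a in zip(deflated, sol.block_loadings):
            np.testing.assert_allclose(X @ a, 0.0, atol=1e-12)

    def test_global_deflation_residual_orthogonal(self, rng):
        blocks = centered_blocks(rng, 9, [5, 3])
        sol = solve_order([b.copy() for b in blocks], DecompositionConfig())
        deflated = deflate(blocks, sol, "global")
        f = sol.global_score
        scale = np.linalg.norm(f)
        for X in deflated:
            for _ in range(5):
                a = rng.standard_normal(X.shape[1])
                assert abs(f @ (X @ a)) <= 1e-10 * scale * np.linalg.norm(X @ a) + 1e-10

    def test_rank_one_block_exhausted(self, rng):
        u = rng.standard_normal(8)
        u -= u.mean()
        v = rng.standard_normal(4)
        X = np.outer(u, v)
        sol = solve_order([X.copy()], DecompositionConfig(tol=1e-13))
        deflated = deflate([X], sol, "block")
        np.testing.assert_allclose(deflated[0], 0.0, atol=1e-12)

    def test_unknown_mode(self, rng):
        blocks = centered_blocks(rng, 6, [3])
        sol = solve_order([b.copy() for b in blocks], DecompositionConfig())
        with pytest.raises(ValueError, match="mode"):
            deflate(blocks, sol, "both")


class TestDecompose:
    def test_single_block_is_pca(self, rng):
        ds = make_dataset(rng, n=12, widths=(6,))
        res = decompose(
            ds,
            PreprocessConfig("center", "none"),
            DecompositionConfig(num_factors=1, tol=1e-13),
        )
        X = ds.blocks[0] - ds.blocks[0].mean(axis=0)
        _, s, Vt = np.linalg.svd(X)
        pc1 = X @ Vt[0]
        got = res.global_scores[:, 0]
        sign = np.sign(pc1 @ got)
        assert np.linalg.norm(got - sign * pc1) < 1e-6 * np.linalg.norm(pc1)

    def test_planted_factor_recovered(self):
        spec = SyntheticSpec(
            n=30,
            block_widths=[50, 20],
            n_factors=1,
            block_signal=np.array([[3.0], [3.0]]),
            noise_sd=0.1,
            seed=7,
        )
        ds, scores, _ = generate(spec)
        res = decompose(ds, config=DecompositionConfig(num_factors=1))
        corr = np.corrcoef(res.global_scores[:, 0], scores[:, 0])[0, 1]
        assert abs(corr) > 0.99

    def test_block_loading_orthonormality(self, rng):
        ds = make_dataset(rng, n=15, widths=(8, 5))
        res = decompose(ds, config=DecompositionConfig(num_factors=3))
        for Ak in res.block_loadings:
            np.testing.assert_allclose(Ak.T @ Ak, np.eye(3), atol=1e-8)

    def test_global_score_orthogonality_under_cpca(self, rng):
        ds = make_dataset(rng, n=15, widths=(8, 5))
        res = decompose(
            ds, config=DecompositionConfig(num_factors=3, deflation="global")
        )
        G = res.global_scores.T @ res.global_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_score_loading_data_identity(self, rng):
        ds = make_dataset(rng, n=12, widths=(6, 4, 3))
        res = decompose(ds, config=DecompositionConfig(num_factors=4))
        pre = apply_preprocessor(res.fitted_preprocessor, ds)
        Xp, _ = concatenate_global(pre)
        scale = np.abs(res.global_scores).max()
        np.testing.assert_allclose(
            Xp @ res.global_loadings, res.global_scores, atol=1e-10 * max(scale, 1)
        )
        for Xk, Ak, Fk in zip(pre.blocks, res.block_loadings, res.block_scores):
            np.testing.assert_allclose(Xk @ Ak, Fk, atol=1e-10 * max(scale, 1))

    def test_deterministic_bitwise(self, rng):
        ds = make_dataset(rng, n=10, widths=(5, 4))
        kwargs = dict(
            preproc=PreprocessConfig("center_scale", "unit_variance"),
            config=DecompositionConfig(num_factors=2, init="random", seed=11),
        )
        r1 = decompose(ds, **kwargs)
        r2 = decompose(ds, **kwargs)
        np.testing.assert_array_equal(r1.global_scores, r2.global_scores, strict=True)
        np.testing.assert_array_equal(
            r1.global_loadings, r2.global_loadings, strict=True
        )

    def test_num_factors_bound_rejected(self, rng):
        ds = make_dataset(rng, n=5, widths=(3, 2))
        with pytest.raises(ValueError, match="num_factors"):
            decompose(ds, config=DecompositionConfig(num_factors=5))

    def test_rank_exhaustion_truncates_with_warning(self):
        spec = SyntheticSpec(
            n=10,
            block_widths=[4, 3],
            n_factors=1,
            block_signal=np.array([[2.0], [2.0]]),
            noise_sd=0.0,
            seed=3,
        )
        ds, _, _ = generate(spec)
        with pytest.warns(RuntimeWarning, match="signal exhausted"):
            res = decompose(
                ds,
                PreprocessConfig("none", "none"),
                DecompositionConfig(num_factors=3),
            )
        assert res.n_factors < 3

    def test_eigenvalues_match_per_order_objectives(self, rng):
        ds = make_dataset(rng, n=12, widths=(6, 4))
        res = decompose(ds, config=DecompositionConfig(num_factors=3))
        for j, sol in enumerate(res.per_order):
            assert res.eigenvalues[j] == sol.eigenvalue == sol.objective_trace[-1]


class TestVarianceExplained:
    def test_single_order_is_one(self, rng):
        ds = make_dataset(rng, n=10, widths=(5,))
        res = decompose(ds, config=DecompositionConfig(num_factors=1))
        np.testing.assert_allclose(variance_explained(res), [1.0])

    def test_sums_to_one(self, rng):
        ds = make_dataset(rng, n=14, widths=(6, 5))
        res = decompose(ds, config=DecompositionConfig(num_factors=4))
        ve = variance_explained(res)
        assert ve.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ve >= 0) and np.all(ve <= 1)

    def test_isotropic_data_near_uniform(self):
        # isotropic Gaussian blocks: no preferred order, proportions ~ 1/R
        rng = np.random.default_rng(5)
        ds = make_dataset(rng, n=500, widths=(6, 6))
        res = decompose(
            ds,
            PreprocessConfig("center_scale", "unit_variance"),
            DecompositionConfig(num_factors=4),
        )
        ve = variance_explained(res)
        np.testing.assert_allclose(ve, 0.25, atol=0.08)

    def test_all_zero_eigenvalues_rejected(self, rng):
        ds = make_dataset(rng, n=10, widths=(5,))
        res = decompose(ds, config=DecompositionConfig(num_factors=1))
        res.eigenvalues = np.zeros(1)
        with pytest.raises(ValueError, match="eigenvalues"):
            variance_explained(res)


class TestBlockContributions:
    def test_single_block_all_ones(self, rng):
        ds = make_dataset(rng, n=10, widths=(5,))
        res = decompose(ds, config=DecompositionConfig(num_factors=2))
        np.testing.assert_allclose(block_contributions(res), np.ones((1, 2)))

    def test_two_identical_blocks_half_half(self, rng):
        X = rng.standard_normal((10, 4))
        ds = make_dataset(rng, n=10, widths=(4, 4))
        ds.blocks = [X.copy(), X.copy()]
        res = decompose(ds, config=DecompositionConfig(num_factors=1))
        np.testing.assert_allclose(block_contributions(res)[:, 0], [0.5, 0.5], atol=1e-8)

    def test_columns_sum_to_one(self, rng):
        ds = make_dataset(rng, n=12, widths=(5, 3, 4))
        res = decompose(ds, config=DecompositionConfig(num_factors=3))
        np.testing.assert_allclose(
            block_contributions(res).sum(axis=0), 1.0, atol=1e-12
        )


class TestTopFeatures:
    @pytest.fixture
    def fake_result(self, rng):
        ds = make_dataset(rng, n=6, widths=(2, 1))
        res = decompose(ds, config=DecompositionConfig(num_factors=1))
        res.global_loadings = np.array([[0.9], [-0.95], [0.1]])
        return res

    def test_sorted_by_absolute_magnitude(self, fake_result):
        feats = top_features(fake_result, order=1, count=2)
        assert [f[2] for f in feats] == [-0.95, 0.9]
        assert feats[0][:2] == ("b1", "b1_f1")

    def test_count_zero_empty(self, fake_result):
        assert top_features(fake_result, order=1, count=0) == []

    def test_count_exceeding_p_returns_all(self, fake_result):
        assert len(top_features(fake_result, order=1, count=99)) == 3

    def test_stable_tie_break(self, fake_result):
        fake_result.global_loadings = np.array([[0.5], [-0.5], [0.5]])
        feats = top_features(fake_result, order=1, count=3)
        assert [f[1] for f in feats] == ["b1_f0", "b1_f1", "b2_f0"]

    def test_order_out_of_range(self, fake_result):
        with pytest.raises(ValueError, match="order"):
            top_features(fake_result, order=2, count=1)


@settings(max_examples=60, deadline=None)
@given(
    seed=st.integers(0, 2**32 - 1),
    n=st.integers(5, 20),
    widths=st.lists(st.integers(2, 10), min_size=1, max_size=3),
    mode=st.sampled_from(["block", "global"]),
)
def test_monotone_convergence_property(seed, n, widths, mode):
    """Objective trace is non-decreasing at every iteration of every order."""
    rng = np.random.default_rng(seed)
    ds = make_dataset(rng, n=n, widths=tuple(widths))
    R = min(3, n - 1, sum(widths))
    res = decompose(
        ds,
        PreprocessConfig("center", "unit_variance"),
        DecompositionConfig(num_factors=R, deflation=mode),
    )
    for sol in res.per_order:
        trace = np.asarray(sol.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)
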