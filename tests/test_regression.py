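"""NIPALS PLSR and coordinate-descent LASSO: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.cross_decomposition import PLSRegression

import gingerspec as gs
from gingerspec.regression import (
    ConvergenceError, _cd_sweeps, default_alpha_grid, kkt_residual,
    predict_scores_pathway,
)


class TestSplit:
    def test_canonical_counts_89_samples(self):
        train, test = gs.split_indices(89, gs.SplitSpec())
        assert test.size == 18 and train.size == 71  # round(0.2 * 89) = 18

    def test_reproducible_for_fixed_seed(self):
        a = gs.split_indices(50, gs.SplitSpec(seed=20))
        b = gs.split_indices(50, gs.SplitSpec(seed=20))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = gs.split_indices(50, gs.SplitSpec(seed=21))
        assert not np.array_equal(a[1], c[1])

    @given(n=st.integers(10, 100))
    def test_partition_is_disjoint_and_exhaustive(self, n):
        train, test = gs.split_indices(n, gs.SplitSpec())
        assert set(train) & set(test) == set()
        assert sorted(set(train) | set(test)) == list(range(n))
        assert test.size == int(np.floor(0.2 * n + 0.5))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            gs.SplitSpec(test_fraction=1.2)


class TestPlsr:
    def test_exact_fit_at_rank(self, rng):
        """A response exactly linear in a rank-3 X is fitted exactly at J=3."""
        scores = rng.normal(size=(30, 3))
        loadings = rng.normal(size=(3, 12))
        X = scores @ loadings
        y = X @ rng.normal(size=12)
        model = gs.fit_plsr(X, y, 3)
        assert np.max(np.abs(model.y_residual)) < 1e-8
        np.testing.assert_allclose(gs.predict(model, X), y, atol=1e-8)

    def test_first_weight_is_normalised_covariance(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        model = gs.fit_plsr(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_expect = Xc.T @ yc
        w_expect /= np.linalg.norm(w_expect)
        np.testing.assert_allclose(model.weights[:, 0], w_expect, atol=1e-12)

    @pytest.mark.parametrize("n_lvs", [1, 3, 5])
    def test_predictions_match_reference_implementation(self, rng, n_lvs):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        ours = gs.predict(gs.fit_plsr(X, y, n_lvs), X)
        ref = PLSRegression(n_components=n_lvs, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_score_columns_orthogonal(self, rng):
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        T = gs.fit_plsr(X, y, 6).x_scores
        gram = T.T @ T
        norms = np.sqrt(np.diag(gram))
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off) / np.outer(norms, norms)) < 1e-8

    def test_bilinear_reconstruction_holds(self, rng):
        X = rng.normal(size=(20, 9))
        y = rng.normal(size=20)
        m = gs.fit_plsr(X, y, 4)
        Xc = X - m.x_mean
        np.testing.assert_allclose(m.x_scores @ m.x_loadings.T + m.x_residual, Xc, atol=1e-10)
        yc = y - m.y_mean
        np.testing.assert_allclose(m.x_scores @ m.y_loadings + m.y_residual, yc, atol=1e-10)

    def test_coefficient_and_scores_pathways_agree(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        m = gs.fit_plsr(X, y, 5)
        Xnew = rng.normal(size=(7, 12))
        np.testing.assert_allclose(gs.predict(m, Xnew), predict_scores_pathway(m, Xnew),
                                   atol=1e-10)

    def test_full_rank_plsr_equals_ols(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        m = gs.fit_plsr(X, y, 6)
        Xc = X - X.mean(axis=0)
        beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(m.coef, beta_ols, atol=1e-8)

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(22, 9))
        y = rng.normal(size=22)
        perm = rng.permutation(22)
        a = gs.fit_plsr(X, y, 3).coef
        b = gs.fit_plsr(X[perm], y[perm], 3).coef
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="zero variance"):
            gs.fit_plsr(X, np.ones(10), 2)
        with pytest.raises(ValueError, match="exceeds"):
            gs.fit_plsr(X, rng.normal(size=10), 10)


class TestLvSelection:
    def test_noiseless_rank_two_response_selects_two(self, rng):
        scores = rng.normal(size=(40, 2))
        X = scores @ rng.normal(size=(2, 15)) + 1e-6 * rng.normal(size=(40, 15))
        y = scores @ np.array([1.5, -0.7])
        j_star, curve = gs.select_lvs_loocv(X, y, max_lvs=8)
        assert j_star == 2

    def test_curve_length_and_argmin(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        j_star, curve = gs.select_lvs_loocv(X, y, max_lvs=6)
        assert curve.size == 6
        assert curve[j_star - 1] == curve.min()
        assert np.all(curve[j_star - 1] <= curve)


class TestPredict:
    def test_training_predictions_reproduce_fitted_values(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        m = gs.fit_plsr(X, y, 3)
        fitted = (y - m.y_mean) - m.y_residual + m.y_mean
        np.testing.assert_allclose(gs.predict(m, X), fitted, atol=1e-10)

    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        m = gs.fit_plsr(X, y, 3)
        assert gs.predict(m, m.x_mean[None, :])[0] == pytest.approx(m.y_mean, abs=1e-12)

    def test_band_count_mismatch_rejected(self, rng):
        m = gs.fit_plsr(rng.normal(size=(15, 6)), rng.normal(size=15), 2)
        with pytest.raises(ValueError, match="bands"):
            gs.predict(m, rng.normal(size=(3, 7)))


class TestLasso:
    def test_alpha_zero_is_least_squares(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        m = gs.fit_lasso(X, y, 0.0)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(m.coef, beta, atol=1e-10)

    def test_alpha_max_zeroes_everything(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        alpha_max = default_alpha_grid(X, y, 2)[0]   # 2 * max |Xc' yc|
        for alpha in (alpha_max, 1.5 * alpha_max):
            assert np.all(gs.fit_lasso(X, y, alpha).coef == 0.0)

    def test_orthonormal_design_matches_soft_threshold(self, rng):
        A = rng.normal(size=(30, 8))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        y = rng.normal(size=30)
        yc = y - y.mean()
        alpha = 0.7
        m = gs.fit_lasso(Q, y, alpha)
        rho = Q.T @ yc
        closed = np.sign(rho) * np.maximum(np.abs(rho) - alpha / 2.0, 0.0)
        np.testing.assert_allclose(m.coef, closed, atol=1e-8)

    def test_kkt_conditions_hold_at_convergence(self, rng):
        X = rng.normal(size=(40, 12))
        y = X @ np.concatenate([np.array([2.0, -1.0]), np.zeros(10)]) + 0.1 * rng.normal(size=40)
        for alpha in (0.5, 2.0, 10.0):
            m = gs.fit_lasso(X, y, alpha)
            assert kkt_residual(m, X, y) < 1e-6

    def test_objective_non_increasing_across_sweeps(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        G, Xty, yty = Xc.T @ Xc, Xc.T @ yc, float(yc @ yc)
        alpha = 1.0
        beta = np.zeros(10)
        objs = []
        for _ in range(20):
            _cd_sweeps(G, Xty, beta, alpha / 2.0, yty, 0.0, 0.0, 0.0, 1)
            r = yc - Xc @ beta
            objs.append(float(r @ r + alpha * np.abs(beta).sum()))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        a = gs.fit_lasso(X, y, 1.0).coef
        b = gs.fit_lasso(X[perm], y[perm], 1.0).coef
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            gs.fit_lasso(rng.normal(size=(10, 3)), rng.normal(size=10), -1.0)

    def test_sweep_budget_exhaustion_raises_with_gap(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        with pytest.raises(ConvergenceError, match="duality gap"):
            gs.fit_lasso(X, y, 0.01, max_iter=1)


class TestAlphaSelection:
    def test_single_value_grid_returned(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        search = gs.select_alpha_cv(X, y, alpha_grid=[3.0])
        assert search.alpha == 3.0
        assert search.cv_rmse.size == 1

    def test_curve_aligned_with_grid(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        grid = [0.1, 1.0, 5.0]
        search = gs.select_alpha_cv(X, y, alpha_grid=grid)
        assert search.cv_rmse.size == 3
        assert search.alpha in grid
        np.testing.assert_array_equal(search.alpha_grid, sorted(grid, reverse=True))

    def test_sparse_truth_recovery_at_snr_20(self):
        """At the LOO-CV-optimal penalty the true support is recovered and
        carries the largest coefficients; the CV-minimum penalty is
        prediction-optimal, not selection-optimal, so some spurious small
        coefficients remain while a good fraction of nulls is zeroed."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 15))
        true_support = [2, 7, 11]
        beta_true = np.zeros(15)
        beta_true[true_support] = [3.0, -2.0, 1.5]
        signal = X @ beta_true
        y = signal + rng.normal(0.0, np.sqrt(signal.var() / 20.0), 40)
        search = gs.select_alpha_cv(X, y)
        m = gs.fit_lasso(X, y, search.alpha)
        active = set(m.active_set.tolist())
        assert set(true_support) <= active
        top3 = set(np.argsort(np.abs(m.coef))[-3:].tolist())
        assert top3 == set(true_support)
        assert len(active) < 15  # genuine sparsification

    def test_default_grid_shape_and_bounds(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        grid = default_alpha_grid(X, y, n_alphas=50, min_ratio=1e-4)
        assert grid.size == 50
        assert grid[0] / grid[-1] == pytest.approx(1e4, rel=1e-9)
        assert np.all(np.diff(grid) < 0)
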