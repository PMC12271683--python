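import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gptransfer import (
    AlignedDesign,
    fit_ridge_analytic,
    fit_ridge_iterative,
    make_lambda_grid,
    penalized_rss,
    predict,
    tune_lambda,
    LambdaGrid,
    RidgeModel,
)
from conftest import random_design


class TestAnalyticSolver:
    def test_identity_design_without_centering(self):
        d = AlignedDesign(np.eye(2), np.array([2.0, 4.0]), ("a", "b"))
        fit = fit_ridge_analytic(d, 1.0, center=False)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0])
        assert fit.intercept == 0.0

    def test_lambda_zero_equals_ols_oracle(self):
        d = random_design(10, 3, seed=0)
        fit = fit_ridge_analytic(d, 0.0)
        Xc = d.X - d.X.mean(0)
        beta = np.linalg.lstsq(Xc, d.y - d.y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-8)

    def test_lambda_zero_singular_system_advises_positive_lambda(self):
        d = random_design(5, 20, seed=1)
        with pytest.raises(np.linalg.LinAlgError, match="positive lambda"):
            fit_ridge_analytic(d, 0.0)

    def test_sklearn_ridge_cross_check(self):
        # independent library oracle on the identical objective scale
        from sklearn.linear_model import Ridge

        d = random_design(15, 40, seed=2)
        lam = 3.7
        fit = fit_ridge_analytic(d, lam)
        sk = Ridge(alpha=lam, fit_intercept=True, solver="cholesky").fit(d.X, d.y)
        np.testing.assert_allclose(fit.coefficients, sk.coef_, rtol=1e-8)
        np.testing.assert_allclose(fit.intercept, sk.intercept_, rtol=1e-8)

    @pytest.mark.parametrize("lam", [1e-3, 1.0, 50.0])
    def test_primal_and_dual_paths_agree(self, lam):
        d = random_design(12, 40, seed=3)  # dual route (p > n)
        fit_dual = fit_ridge_analytic(d, lam)
        Xc = d.X - d.X.mean(0)
        beta_primal = np.linalg.solve(Xc.T @ Xc + lam * np.eye(d.p),
                                      Xc.T @ (d.y - d.y.mean()))
        np.testing.assert_allclose(fit_dual.coefficients, beta_primal, rtol=1e-8)

    def test_primal_dual_equality_along_whole_grid(self):
        d = random_design(12, 40, seed=4)
        grid = make_lambda_grid(d, n_values=25)
        for lam in grid.values:
            fit = fit_ridge_analytic(d, lam)
            Xc = d.X - d.X.mean(0)
            beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(d.p),
                                   Xc.T @ (d.y - d.y.mean()))
            np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-8, atol=1e-12)

    def test_reconstruction_identity_on_raw_scale(self):
        d = random_design(20, 8, seed=5)
        fit = fit_ridge_analytic(d, 2.0)
        Xc = d.X - fit.x_means
        internal = d.y.mean() + Xc @ fit.coefficients
        np.testing.assert_allclose(predict(fit, d.X), internal, rtol=1e-8)

    def test_non_finite_inputs_rejected(self):
        d = random_design(6, 3, seed=6)
        d.X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_ridge_analytic(d, 1.0)


class TestIterativeSolver:
    @pytest.mark.parametrize("n,p,lam", [(20, 8, 0.5), (12, 30, 4.0), (30, 30, 100.0)])
    def test_matches_analytic_solution(self, n, p, lam):
        d = random_design(n, p, seed=n + p)
        fa = fit_ridge_analytic(d, lam)
        fi = fit_ridge_iterative(d, lam)
        np.testing.assert_allclose(fi.coefficients, fa.coefficients,
                                   rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(fi.intercept, fa.intercept, rtol=1e-6)

    def test_zero_response_gives_zero_fit(self):
        d = random_design(10, 5, seed=7, y=np.zeros(10))
        fit = fit_ridge_iterative(d, 1.0)
        np.testing.assert_array_equal(fit.coefficients, 0.0)
        assert fit.intercept == 0.0

    def test_extreme_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        X = (X - X.mean(0)) / X.std(0)
        d = AlignedDesign(X, rng.normal(size=30), tuple(f"L{i}" for i in range(30)))
        fit = fit_ridge_iterative(d, 1e9)
        assert np.abs(fit.coefficients).max() < 1e-5

    def test_non_convergence_carries_last_iterate(self):
        d = random_design(10, 6, seed=9)
        with pytest.raises(RuntimeError, match="did not converge") as exc:
            fit_ridge_iterative(d, 0.5, tol=1e-14, max_iter=1)
        assert hasattr(exc.value, "last_coefficients")


class TestObjectiveProperties:
    def test_shrinkage_norm_monotone_in_lambda(self):
        for seed in range(20):
            d = random_design(15, 25, seed=100 + seed)
            grid = make_lambda_grid(d, n_values=100)
            norms = [np.linalg.norm(fit_ridge_analytic(d, lam).coefficients)
                     for lam in grid.values]  # grid is decreasing in λ
            assert all(a <= b + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_fitted_coefficients_minimize_prss(self):
        d = random_design(18, 12, seed=10)
        lam = 2.5
        fit = fit_ridge_analytic(d, lam)
        base = penalized_rss(d, fit.intercept, fit.coefficients, lam)
        rng = np.random.default_rng(11)
        for _ in range(50):
            step = rng.normal(size=d.p)
            step *= 1e-3 / np.linalg.norm(step)
            perturbed = fit.coefficients + step
            intercept = d.y.mean() - d.X.mean(0) @ perturbed
            assert penalized_rss(d, intercept, perturbed, lam) >= base

    def test_infinite_penalty_limit_predicts_train_mean(self):
        d = random_design(15, 10, seed=12)
        fit = fit_ridge_analytic(d, 1e14)
        np.testing.assert_allclose(predict(fit, d.X), np.full(d.n, d.y.mean()),
                                   atol=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(4, 15), p=st.integers(1, 12),
           lam=st.floats(1e-3, 1e3))
    def test_stationarity_of_penalized_normal_equations(self, seed, n, p, lam):
        """At the optimum, Xcᵀ(yc − Xc β̂) = λ β̂ (gradient of PRSS is zero)."""
        d = random_design(n, p, seed=seed)
        fit = fit_ridge_analytic(d, lam)
        Xc = d.X - d.X.mean(0)
        grad_gap = Xc.T @ (d.y - d.y.mean() - Xc @ fit.coefficients) - lam * fit.coefficients
        scale = max(1.0, np.linalg.norm(fit.coefficients)) * max(lam, 1.0)
        assert np.abs(grad_gap).max() <= 1e-7 * scale


class TestLambdaGrid:
    def test_construction_size_and_ratio(self):
        d = random_design(20, 10, seed=13)
        grid = make_lambda_grid(d, n_values=100, min_ratio=1e-4)
        assert grid.n_values == 100
        assert (np.diff(grid.values) < 0).all()
        np.testing.assert_allclose(grid.values[-1] / grid.values[0], 1e-4, rtol=1e-12)

    def test_anchor_scales_linearly_with_response(self):
        d = random_design(20, 10, seed=14)
        d10 = AlignedDesign(d.X, 10 * d.y, d.line_ids)
        np.testing.assert_allclose(make_lambda_grid(d10).values,
                                   10 * make_lambda_grid(d).values, rtol=1e-10)

    def test_constant_design_rejected(self):
        d = AlignedDesign(np.ones((5, 3)), np.arange(5.0), tuple("abcde"))
        with pytest.raises(ValueError, match="constant"):
            make_lambda_grid(d)


class TestTuneLambda:
    def test_singleton_grid_returns_its_value(self):
        d = random_design(25, 5, seed=15)
        cv = tune_lambda(d, LambdaGrid(np.array([3.5]), 0.5), seed=0)
        assert cv.lambda_star == 3.5
        assert len(cv.table) == 1

    def test_exact_tie_resolves_to_larger_lambda(self):
        d = random_design(25, 5, seed=16)
        grid = LambdaGrid(np.array([2.0, 2.0 - 1e-15]), 0.5)  # numerically equal MSEs
        cv = tune_lambda(d, grid, seed=0)
        assert cv.lambda_star == 2.0

    def test_noiseless_overdetermined_prefers_smallest_decade(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 5))
        beta = rng.normal(size=5)
        d = AlignedDesign(X, X @ beta, tuple(f"L{i}" for i in range(60)))
        grid = make_lambda_grid(d, n_values=100)
        cv = tune_lambda(d, grid, seed=3)
        assert cv.lambda_star <= grid.values[-1] * 10  # bottom decade of the grid

    def test_degenerate_split_skipped_with_warning(self):
        y = np.zeros(10)
        y[0] = 1.0  # most inner-train splits are constant
        d = random_design(10, 3, seed=18, y=y)
        grid = LambdaGrid(np.array([1.0]), 0.5)
        with pytest.warns(UserWarning, match="constant response"):
            cv = tune_lambda(d, grid, n_splits=20, seed=0)
        assert cv.n_skipped > 0

    def test_mean_mse_table_matches_per_lambda_refits(self):
        """The eigendecomposition path must equal brute-force per-λ refitting."""
        from gptransfer.ridge import _inner_splits

        d = random_design(24, 40, seed=19)
        grid = make_lambda_grid(d, n_values=12)
        cv = tune_lambda(d, grid, n_splits=5, seed=7)
        brute = np.zeros((5, 12))
        for s, (tr, va) in enumerate(_inner_splits(d.n, 5, 0.2, 7)):
            sub = d.subset(tr)
            for k, lam in enumerate(grid.values):
                pred = predict(fit_ridge_analytic(sub, lam), d.X[va])
                brute[s, k] = ((pred - d.y[va]) ** 2).mean()
        np.testing.assert_allclose(cv.table["mean_mse"], brute.mean(0), rtol=1e-8)

    def test_iterative_solver_pathway_agrees_with_analytic(self):
        d = random_design(20, 6, seed=20)
        grid = make_lambda_grid(d, n_values=8)
        cv_a = tune_lambda(d, grid, n_splits=3, seed=1, solver="analytic")
        cv_i = tune_lambda(d, grid, n_splits=3, seed=1, solver="iterative")
        np.testing.assert_allclose(cv_i.table["mean_mse"], cv_a.table["mean_mse"],
                                   rtol=1e-5)
        assert cv_i.lambda_star == cv_a.lambda_star


class TestPredictAndModelApi:
    def test_single_row_and_column_mismatch(self):
        d = random_design(10, 4, seed=21)
        fit = fit_ridge_analytic(d, 1.0)
        assert predict(fit, d.X[0]).shape == (1,)
        with pytest.raises(ValueError, match="columns"):
            predict(fit, np.zeros((3, 5)))

    def test_zero_coefficient_fit_predicts_constant(self):
        d = random_design(10, 4, seed=22, y=np.full(10, 3.25))
        fit = fit_ridge_analytic(d, 5.0)
        np.testing.assert_allclose(predict(fit, np.zeros((4, 4))), 3.25)

    def test_model_fit_tunes_then_matches_direct_fit(self):
        d = random_design(30, 12, seed=23)
        res = RidgeModel.from_design(d).fit(seed=4)
        assert res.inner_cv is not None
        direct = fit_ridge_analytic(d, res.lam)
        np.testing.assert_allclose(res.params, direct.coefficients, rtol=1e-10)
        assert "Ridge Regression Results" in res.summary()
        assert f"{res.lam:.6g}" in res.summary()
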