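"""Numerical primitives: ridge, penalty selection, factor analysis, PCA,
normality testing."""

import numpy as np
import pytest
from scipy import optimize

from likingdqi.errors import ConstantColumnError, RankDeficiencyError
from likingdqi.stats import (RidgeSpec, default_lambda_grid, factor_varimax,
                             fit_ridge, kfold_indices, ks_normality,
                             pca_first, select_lambda)


def _random_system(seed, n=50, p=8):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    y = X @ r.normal(size=p) + r.normal(size=n)
    return X, y


class TestRidge:
    def test_unpenalized_limit_equals_ols(self):
        X, y = _random_system(0)
        fit = fit_ridge(X, y, RidgeSpec(lam=0.0, standardize=False))
        A = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-8)
        np.testing.assert_allclose(
            fit.intercept + 0 * beta[0],
            beta[0] + X.mean(axis=0) @ beta[1:], atol=1e-8)

    def test_infinite_penalty_limit(self):
        X, y = _random_system(1)
        fit = fit_ridge(X, y, RidgeSpec(lam=1e9))
        assert np.linalg.norm(fit.coef) < 1e-3
        assert fit.intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numeric_minimizer_of_objective(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(5, 3))
        y = r.normal(size=5)
        lam = 2.0
        fit = fit_ridge(X, y, RidgeSpec(lam=lam, standardize=False))

        def objective(params):
            b0, b = params[0], params[1:]
            resid = y - b0 - X @ b
            return resid @ resid + lam * (b @ b)

        res = optimize.minimize(objective, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(fit.coef, res.x[1:], atol=1e-6)
        np.testing.assert_allclose(
            fit.predict(X), res.x[0] + X @ res.x[1:], atol=1e-6)

    def test_agrees_with_sklearn_ridge(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = _random_system(3)
        lam = 7.5
        fit = fit_ridge(X, y, RidgeSpec(lam=lam, standardize=False))
        sk = sklearn_linear.Ridge(alpha=lam, fit_intercept=True).fit(X, y)
        np.testing.assert_allclose(fit.coef, sk.coef_, atol=1e-8)

    def test_coefficient_norm_shrinks_monotonically_in_lambda(self):
        X, y = _random_system(4)
        grid = [0.0, 0.1, 1.0, 10.0, 100.0, 1e4]
        norms = [np.linalg.norm(fit_ridge(X, y, RidgeSpec(lam=l)).coef)
                 for l in grid]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_rank_deficiency_error_at_lambda_zero_only(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # collinear
        y = r.normal(size=20)
        with pytest.raises(RankDeficiencyError):
            fit_ridge(X, y, RidgeSpec(lam=0.0, standardize=False))
        fit = fit_ridge(X, y, RidgeSpec(lam=1e-6, standardize=False))
        assert np.all(np.isfinite(fit.coef))

    def test_penalty_mask_spares_unpenalized_columns(self):
        X, y = _random_system(6)
        mask = (True,) * 7 + (False,)
        heavy = fit_ridge(X, y, RidgeSpec(lam=1e8, penalized=mask))
        assert np.linalg.norm(heavy.coef[:7]) < 1e-3
        # the unpenalized column keeps a non-trivial coefficient
        assert abs(heavy.coef[7]) > 1e-3


class TestSelectLambda:
    def test_single_element_grid_forced_choice(self):
        X, y = _random_system(0, n=40)
        assert select_lambda(X, y, grid=[3.3], seed=0) == 3.3

    def test_noiseless_linear_signal_picks_grid_minimum(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        grid = default_lambda_grid(20)
        assert select_lambda(X, y, grid=grid, seed=0) == pytest.approx(grid[0])

    def test_pure_noise_outcome_prefers_heavy_shrinkage(self):
        grid = default_lambda_grid(20)
        top_quartile = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            X = r.normal(size=(60, 6))
            y = r.normal(size=60)
            lam = select_lambda(X, y, grid=grid, seed=seed)
            if lam >= grid[-6]:
                top_quartile += 1
        assert top_quartile >= 11  # majority of replicates

    def test_fold_assignment_depends_only_on_inputs(self):
        a = kfold_indices(100, 5, 9)
        b = kfold_indices(100, 5, 9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        sizes = sorted(len(f) for f in a)
        assert sizes == [20] * 5


class TestFactorVarimax:
    @staticmethod
    def _block_data(n=2000, seed=0):
        r = np.random.default_rng(seed)
        f1, f2 = r.normal(size=(2, n))
        eps = 1e-4 * r.normal(size=(n, 6))  # near-perfect blocks
        X = np.column_stack([f1, f1, f1, f2, f2, f2]) + eps
        return X

    def test_block_structure_separates_cleanly(self):
        fm = factor_varimax(self._block_data(), n_factors=2)
        L = np.abs(fm.loadings.to_numpy())
        block1, block2 = L[:3], L[3:]
        own1 = np.argmax(block1.sum(axis=0))
        assert np.all(block1[:, own1] >= 0.99)
        assert np.all(block1[:, 1 - own1] <= 0.01)
        assert np.all(block2[:, 1 - own1] >= 0.99)
        assert np.all(block2[:, own1] <= 0.01)

    def test_recovers_population_solution_of_planted_model(self):
        # data from a planted 2-factor model; the oracle is the population
        # extraction+rotation evaluated on the true correlation matrix
        r = np.random.default_rng(42)
        n = 20000
        planted = np.array([[0.8, 0.0], [0.7, 0.1], [0.0, 0.8], [0.1, 0.7]])
        unique = np.sqrt(1 - (planted ** 2).sum(axis=1))
        sigma = planted @ planted.T + np.diag(unique ** 2)
        eigval, eigvec = np.linalg.eigh(sigma)
        order = np.argsort(eigval)[::-1][:2]
        from likingdqi.stats import _varimax
        pop_L, _ = _varimax(eigvec[:, order] * np.sqrt(eigval[order]))

        F = r.normal(size=(n, 2))
        X = F @ planted.T + r.normal(size=(n, 4)) * unique
        fm = factor_varimax(X, n_factors=2)
        L = fm.loadings.to_numpy()
        best = min(
            np.abs(np.abs(L[:, perm]) - np.abs(pop_L)).max()
            for perm in ([0, 1], [1, 0]))
        assert best < 0.05

    def test_rotation_is_orthonormal_and_preserves_communality(self,
                                                               default_cohort):
        fm = factor_varimax(default_cohort.survey.iloc[:, :20], n_factors=4)
        R = fm.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(4), atol=1e-8)
        assert fm.variance_explained.sum() <= 1 + 1e-9
        # explained variance ordering
        assert np.all(np.diff(fm.variance_explained) <= 1e-12)

    def test_sign_convention_largest_loading_positive(self):
        fm = factor_varimax(self._block_data(seed=5), n_factors=2)
        L = fm.loadings.to_numpy()
        for j in range(2):
            assert L[np.abs(L[:, j]).argmax(), j] > 0

    def test_two_factor_rotation_matches_brute_force_angle(self):
        # independent oracle: scan the single free rotation angle
        r = np.random.default_rng(9)
        X = r.normal(size=(500, 5)) @ r.normal(size=(5, 5))
        fm = factor_varimax(X, n_factors=2)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        R = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1][:2]
        L = eigvec[:, order] * np.sqrt(eigval[order])
        h = np.sqrt((L ** 2).sum(axis=1))
        Ln = L / h[:, None]
        p = L.shape[0]

        def criterion(theta):
            c, s = np.cos(theta), np.sin(theta)
            Lr = Ln @ np.array([[c, -s], [s, c]])
            return (Lr ** 4).sum() - ((Lr ** 2).sum(axis=0) ** 2).sum() / p

        best = max(criterion(t) for t in np.linspace(0, np.pi / 2, 200001))
        Lfit = (fm.loadings.to_numpy() / h[:, None])
        got = (Lfit ** 4).sum() - ((Lfit ** 2).sum(axis=0) ** 2).sum() / p
        assert got == pytest.approx(best, abs=1e-6)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), np.arange(50.0) ** 2])
        with pytest.raises(ConstantColumnError):
            factor_varimax(X, n_factors=2)


class TestPCA:
    @pytest.mark.parametrize("r", np.round(np.arange(-0.9, 0.91, 0.2), 2))
    def test_two_variable_explained_fraction_closed_form(self, r):
        # construct data whose sample correlation is exactly r
        n = 64
        t = np.arange(n)
        u = np.cos(2 * np.pi * t / n)
        v = np.sin(2 * np.pi * t / n)
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        x = u
        y = r * u + np.sqrt(1 - r ** 2) * v
        res = pca_first(np.column_stack([x, y]))
        assert res.explained_fraction[0] == pytest.approx(
            (1 + abs(r)) / 2, abs=1e-6)

    def test_identical_columns_rank_one(self, rng):
        col = rng.normal(size=100)
        res = pca_first(np.column_stack([col, col, col]))
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variables_isotropic(self, rng):
        X = rng.normal(size=(100000, 4))
        res = pca_first(X)
        assert res.explained_fraction[0] == pytest.approx(0.25, abs=0.02)

    def test_constant_column_named_in_error(self):
        import pandas as pd
        X = pd.DataFrame({"a": np.arange(20.0), "flat": np.ones(20)})
        with pytest.raises(ConstantColumnError, match="flat"):
            pca_first(X)


class TestKSNormality:
    def test_level_on_normal_draws(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(3.0, 2.0, 1000)
            _, p = ks_normality(x)
            rejections += p <= 0.05
        assert rejections <= 10  # holds level: >= 90% non-rejections

    def test_power_on_exponential_draws(self):
        x = np.random.default_rng(0).exponential(size=5000)
        _, p = ks_normality(x)
        assert p < 0.001

    def test_statistic_affine_invariant(self, rng):
        x = rng.normal(size=500)
        d1, _ = ks_normality(x)
        d2, _ = ks_normality(5.0 * x - 7.0)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(5.0))
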