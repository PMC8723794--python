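"""Gaussian process regression and the task-to-total score mapping."""

import numpy as np
import pytest

from rehabfuse.estimators import (FAS_INTERCEPT, FAS_MAX_POINTS, FAS_SLOPE,
                                  GPRConfig, GPRModel, Standardizer,
                                  clinical_post_estimate, estimate_task_scores,
                                  gpr_fit, gpr_predict, invert_total_fas_percent,
                                  loo_block_predict, total_fas_percent)
from rehabfuse.synthgen import TASK_IDS


def _fixed_cfg(**kw):
    defaults = dict(optimize=False, sigma_f=1.5, length_scale=0.8, sigma_n=0.3,
                    jitter=0.0, include_noise_in_variance=False)
    defaults.update(kw)
    return GPRConfig(**defaults)


class TestGPRCore:
    def test_two_point_closed_form(self):
        # hand-computed 2x2 posterior algebra
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 2.0])
        model = gpr_fit(X, y, _fixed_cfg())
        xs = np.array([[0.4]])
        k = lambda a, b: 1.5**2 * np.exp(-0.5 * (a - b) ** 2 / 0.8**2)
        K = np.array([[k(0, 0) + 0.09, k(0, 1)], [k(1, 0), k(1, 1) + 0.09]])
        ks = np.array([k(0, 0.4), k(1, 0.4)])
        yc = y - y.mean()
        mean_cf = y.mean() + ks @ np.linalg.solve(K, yc)
        var_cf = k(0.4, 0.4) - ks @ np.linalg.solve(K, ks)
        mu, var = gpr_predict(model, xs)
        assert mu[0] == pytest.approx(mean_cf, abs=1e-8)
        assert var[0] == pytest.approx(var_cf, abs=1e-8)

    def test_matches_naive_dense_recomputation(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = gpr_fit(X, y, _fixed_cfg())
        Xs = rng.normal(size=(4, 2))
        # naive O(n^3) oracle
        def k(A, B):
            d = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
            return 1.5**2 * np.exp(-0.5 * d / 0.8**2)
        K = k(X, X) + 0.09 * np.eye(15)
        Ks = k(X, Xs)
        mu_naive = y.mean() + Ks.T @ np.linalg.solve(K, y - y.mean())
        var_naive = np.diag(k(Xs, Xs) - Ks.T @ np.linalg.solve(K, Ks))
        mu, var = gpr_predict(model, Xs)
        assert np.allclose(mu, mu_naive, atol=1e-10)
        assert np.allclose(var, var_naive, atol=1e-10)

    def test_matches_sklearn_fixed_kernel(self, rng):
        # independent implementation cross-check with fixed hyperparameters
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel
        X = rng.normal(size=(20, 3))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        model = gpr_fit(X, y, _fixed_cfg(sigma_f=1.2, length_scale=1.5, sigma_n=0.2))
        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(1.2**2, "fixed") * RBF(1.5, "fixed"),
            alpha=0.04, optimizer=None, normalize_y=True)
        sk.fit(X, y)
        Xs = rng.normal(size=(5, 3))
        mu, _ = gpr_predict(model, Xs)
        assert np.allclose(mu, sk.predict(Xs), atol=1e-6)

    def test_interpolation_limit_small_noise(self, rng):
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        model = gpr_fit(X, y, _fixed_cfg(sigma_n=1e-6, jitter=1e-12))
        mu, _ = gpr_predict(model, X)
        assert np.allclose(mu, y, atol=1e-4)

    def test_prior_reversion_far_from_data(self):
        X = np.zeros((5, 1))
        y = np.array([1.0, 2.0, 3.0, 2.0, 2.0])
        model = gpr_fit(X, y, _fixed_cfg())
        mu, var = gpr_predict(model, np.array([[100.0]]))
        assert mu[0] == pytest.approx(y.mean(), abs=1e-9)
        assert var[0] == pytest.approx(1.5**2, abs=1e-9)

    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(8, 2))
        model = gpr_fit(X, np.full(8, 4.2))
        mu, _ = gpr_predict(model, rng.normal(size=(3, 2)))
        assert np.allclose(mu, 4.2, atol=1e-6)

    def test_refit_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0]) + 0.2 * rng.normal(size=30)
        m1 = gpr_fit(X, y, seed=5)
        m2 = gpr_fit(X, y, seed=5)
        assert (m1.sigma_f, m1.length_scale, m1.sigma_n) == \
            (m2.sigma_f, m2.length_scale, m2.sigma_n)

    def test_schema_mismatch_rejected(self, rng):
        model = gpr_fit(rng.normal(size=(5, 2)), rng.normal(size=5), _fixed_cfg())
        with pytest.raises(ValueError, match="columns"):
            gpr_predict(model, rng.normal(size=(2, 3)))

    def test_target_shift_shifts_predictions(self, rng):
        # mean-centering: adding a constant to all targets shifts all
        # predictions by the same constant
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        Xs = rng.normal(size=(6, 2))
        m0 = gpr_fit(X, y, _fixed_cfg())
        m1 = gpr_fit(X, y + 7.5, _fixed_cfg())
        mu0, _ = gpr_predict(m0, Xs)
        mu1, _ = gpr_predict(m1, Xs)
        assert np.allclose(mu1 - mu0, 7.5, atol=1e-9)

    def test_block_loo_matches_refit(self, rng):
        # leaving a block out via the closed form must equal predicting
        # with a model refit without that block (same hyperparameters and
        # prior mean)
        X = rng.normal(size=(24, 2))
        y = np.sin(X[:, 0]) + 0.3 * rng.normal(size=24)
        cfg = _fixed_cfg(include_noise_in_variance=True)
        model = gpr_fit(X, y, cfg)
        block = np.array([3, 4, 5])
        (mu_b,), (cov_b,) = loo_block_predict(model, [block])
        keep = np.setdiff1d(np.arange(24), block)
        refit = gpr_fit(X[keep], y[keep], cfg)
        refit.y_mean = model.y_mean   # same prior mean as the full model
        refit.alpha = np.linalg.solve(
            refit.kernel(refit.X, refit.X) + 0.09 * np.eye(keep.size),
            y[keep] - model.y_mean)
        mu_ref, cov_ref = gpr_predict(refit, X[block], full_cov=True)
        assert np.allclose(mu_b, mu_ref, atol=1e-8)
        assert np.allclose(cov_b, cov_ref, atol=1e-8)

    def test_parameter_recovery(self):
        # draws from a known squared-exponential GP: the fitted length-scale
        # is within a factor of 2 of truth in >= 80% of seeds
        ell_true, sf_true, sn_true = 1.0, 2.0, 0.2
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-3, 3, size=(100, 1))
            d = (X - X.T) ** 2
            K = sf_true**2 * np.exp(-0.5 * d / ell_true**2)
            f = rng.multivariate_normal(np.zeros(100), K + 1e-10 * np.eye(100))
            y = f + sn_true * rng.normal(size=100)
            model = gpr_fit(X, y, seed=seed)
            if ell_true / 2 <= model.length_scale <= ell_true * 2:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        model = gpr_fit(X, y, _fixed_cfg())
        back = GPRModel.from_json(model.to_json())
        Xs = rng.normal(size=(3, 2))
        assert np.allclose(gpr_predict(model, Xs)[0], gpr_predict(back, Xs)[0])


class TestTaskScores:
    def test_mean_of_repetitions(self):
        preds = {t: np.array([3.0, 4.0, 5.0]) for t in TASK_IDS}
        ts = estimate_task_scores(preds)
        assert np.allclose(ts.task_scores, 4.0)

    def test_clipping_and_constant(self):
        preds = {t: np.array([5.3]) for t in TASK_IDS}
        assert np.allclose(estimate_task_scores(preds).task_scores, 5.0)
        preds = {t: np.array([2.2, 2.2]) for t in TASK_IDS}
        assert np.allclose(estimate_task_scores(preds).task_scores, 2.2)

    def test_missing_task_rejected(self):
        preds = {t: np.array([3.0]) for t in TASK_IDS[:-1]}
        with pytest.raises(ValueError, match="no repetition"):
            estimate_task_scores(preds)


class TestTotalFas:
    def test_intercept_at_zero(self):
        assert total_fas_percent(0.0) * FAS_MAX_POINTS / 100.0 == \
            pytest.approx(FAS_INTERCEPT)

    def test_slope_per_unit(self):
        p1 = total_fas_percent(1.0) * FAS_MAX_POINTS / 100.0
        p0 = total_fas_percent(0.0) * FAS_MAX_POINTS / 100.0
        assert p1 - p0 == pytest.approx(FAS_SLOPE)

    def test_full_scale_value(self):
        # 40 x 1.78 + 2.97 = 74.17 points = 98.89% of 75
        assert total_fas_percent(40.0) == pytest.approx(74.17 / 75.0 * 100.0,
                                                        abs=1e-9)

    def test_affine_strictly_increasing(self):
        grid = np.linspace(0, 40, 101)
        vals = np.array([total_fas_percent(g) for g in grid])
        assert np.all(np.diff(vals) > 0)
        # affine: second differences vanish
        assert np.allclose(np.diff(vals, 2), 0.0, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_fas_percent(41.0)

    def test_inverse_round_trip(self):
        for v in (0.0, 10.0, 25.0, 40.0):
            assert invert_total_fas_percent(total_fas_percent(v)) == \
                pytest.approx(v, abs=1e-9)


class TestClinicalEstimate:
    def test_zero_change_model_returns_baseline(self, rng):
        X = rng.normal(size=(10, 6))
        model = gpr_fit(X, np.zeros(10))
        scaler = Standardizer(np.zeros(6), np.ones(6))
        est = clinical_post_estimate(rng.normal(size=6), 55.0, model, scaler)
        assert est.mean == pytest.approx(55.0, abs=1e-6)

    def test_variance_nonnegative_sweep(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = gpr_fit(X, y, _fixed_cfg(include_noise_in_variance=True))
        scaler = Standardizer.fit(X)
        for _ in range(200):
            est = clinical_post_estimate(rng.normal(size=6) * 5, 50.0, model, scaler)
            assert est.variance >= 0.0

    def test_missing_covariate_rejected(self, rng):
        model = gpr_fit(rng.normal(size=(5, 6)), rng.normal(size=5), _fixed_cfg())
        scaler = Standardizer(np.zeros(6), np.ones(6))
        with pytest.raises(ValueError, match="covariates"):
            clinical_post_estimate(np.ones(5), 50.0, model, scaler)
        with pytest.raises(ValueError, match="finite"):
            clinical_post_estimate(np.array([1, 2, 3, 4, 5, np.nan]), 50.0,
                                   model, scaler)
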