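"""Constrained-QP fusion and the benchmark combiners."""

import numpy as np
import pytest

from rehabfuse.estimators import Standardizer
from rehabfuse.fusion import (FusionTrainingSet, assemble_qp, averaging_weights,
                              fit_fusion, fuse_predict, upper_bound_select,
                              variance_weights)


def _random_training(rng, n=8, m=2, centered=False):
    X = rng.normal(size=(n, m))
    if centered:
        X = (X - X.mean(0)) / X.std(0)
    else:
        X = 0.5 + 0.2 * X
    y_c = 60 + 10 * rng.normal(size=n)
    y_s = y_c + 6 * rng.normal(size=n)
    y = 0.5 * y_c + 0.5 * y_s + rng.normal(size=n)
    return FusionTrainingSet(X, y_c, y_s, y)


def grid_search_qp(qp, step=1e-3, box=3.0):
    """Independent oracle: exhaustive feasible grid search (m <= 2)."""
    m = qp.A.shape[1]
    if m == 1:
        # the feasible set is an interval; intersect the half-planes exactly
        lo, hi = -box, box
        for xi in qp.X_c[:, 0]:
            if xi > 0:
                lo, hi = max(lo, 0.0), min(hi, 1.0 / xi)
            elif xi < 0:
                lo, hi = max(lo, 1.0 / xi), min(hi, 0.0)
        grid = np.arange(lo, hi, step)
        feasible = np.append(grid, hi)[:, None]   # include the exact endpoint
    else:
        # coarse pass to localize the feasible polygon, then the 1e-3 grid
        coarse = np.arange(-box, box + 0.02, 0.02)
        T = np.array(np.meshgrid(coarse, coarse)).reshape(2, -1).T
        W = qp.X_c @ T.T
        ok = ((W >= -1e-12) & (W <= 1 + 1e-12)).all(axis=0)
        pts = T[ok]
        lo = pts.min(axis=0) - 0.05
        hi = pts.max(axis=0) + 0.05
        g0 = np.arange(lo[0], hi[0] + step, step)
        g1 = np.arange(lo[1], hi[1] + step, step)
        best = (np.inf, None)
        for chunk in np.array_split(g0, max(1, g0.size // 200)):
            T = np.array(np.meshgrid(chunk, g1)).reshape(2, -1).T
            W = qp.X_c @ T.T
            ok = ((W >= 0) & (W <= 1)).all(axis=0)
            if not ok.any():
                continue
            Tf = T[ok]
            J = np.einsum("ij,jk,ik->i", Tf, qp.A.T @ qp.A, Tf) \
                - 2.0 * (qp.b @ qp.A) @ Tf.T
            i = int(np.argmin(J))
            if J[i] < best[0]:
                best = (float(J[i]), Tf[i])
        return best[1], best[0]
    J = np.array([qp.objective(t) for t in feasible])
    i = int(np.argmin(J))
    return feasible[i], float(J[i])


class TestAssembly:
    def test_row_scaling(self):
        tr = FusionTrainingSet(np.array([[1.0], [-1.0]]),
                               np.array([62.0, 62.0]), np.array([60.0, 60.0]),
                               np.array([61.0, 61.0]))
        qp = assemble_qp(tr)
        assert np.allclose(qp.A, [[2.0], [-2.0]])
        assert np.allclose(qp.b, [1.0, 1.0])

    def test_equal_estimates_degenerate(self, rng):
        X = rng.normal(size=(5, 2))
        y_c = 50 + rng.normal(size=5)
        qp = assemble_qp(FusionTrainingSet(X, y_c, y_c, y_c + 1))
        assert np.allclose(qp.A, 0.0)
        assert qp.objective(rng.normal(size=2)) == pytest.approx(0.0)

    def test_objective_equals_residual_identity(self, rng):
        # J(theta) = ||b - A theta||^2 - ||b||^2 by expansion
        for _ in range(20):
            tr = _random_training(rng)
            qp = assemble_qp(tr)
            th = rng.normal(size=2)
            assert qp.objective(th) == pytest.approx(
                qp.residual_norm_sq(th) - float(qp.b @ qp.b), rel=1e-9, abs=1e-9)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_qp(FusionTrainingSet(np.zeros((0, 2)), [], [], []))


class TestFit:
    def test_zero_residual_optimum(self, rng):
        tr = _random_training(rng)
        tr = FusionTrainingSet(tr.X_c, tr.y_c, tr.y_s, tr.y_s)  # y == y_s
        model = fit_fusion(tr)
        qp = assemble_qp(tr)
        assert qp.objective(model.theta) <= 1e-10

    def test_m1_matches_grid_search(self, rng):
        for _ in range(10):
            tr = _random_training(rng, n=5, m=1)
            model = fit_fusion(tr, ridge=0.0)
            qp = assemble_qp(tr)
            _, J_grid = grid_search_qp(qp)
            assert qp.objective(model.theta) <= J_grid + 1e-6
            assert qp.constraint_violation(model.theta) <= 1e-8

    def test_m2_beats_random_feasible_points(self, rng):
        tr = _random_training(rng, n=8, m=2)
        model = fit_fusion(tr, ridge=0.0)
        qp = assemble_qp(tr)
        J_star = qp.objective(model.theta)
        found_feasible = 0
        for _ in range(100_000):
            th = rng.normal(size=2) * 2
            if qp.constraint_violation(th) <= 0:
                found_feasible += 1
                assert J_star <= qp.objective(th) + 1e-6
        assert found_feasible > 100

    def test_feasibility_on_random_instances(self, rng):
        # constraints hold at theta* across sizes, centered and uncentered
        for i in range(60):
            n = int(rng.integers(6, 50))
            m = int(rng.integers(1, 7))
            tr = _random_training(rng, n=n, m=m, centered=bool(i % 2))
            model = fit_fusion(tr)
            qp = assemble_qp(tr)
            assert qp.constraint_violation(model.theta) <= 1e-8

    def test_weight_recovery_r2(self, rng):
        # planted feasible theta with noisy targets: fitted fused values
        # match noiseless fused values with R^2 >= 0.98
        n, m = 200, 6
        X = 0.5 + 0.15 * rng.normal(size=(n, m))
        theta_true = np.array([0.3, 0.2, 0.15, 0.1, 0.05, 0.05])
        w = X @ theta_true
        assert w.min() >= 0 and w.max() <= 1
        y_c = 60 + 15 * rng.normal(size=n)
        y_s = y_c + 8 * rng.normal(size=n)
        noiseless = w * y_c + (1 - w) * y_s
        y = noiseless + 0.5 * rng.normal(size=n)
        model = fit_fusion(FusionTrainingSet(X, y_c, y_s, y))
        w_fit = np.clip(X @ model.theta, 0, 1)
        fitted = w_fit * y_c + (1 - w_fit) * y_s
        r2 = 1 - np.sum((fitted - noiseless) ** 2) / \
            np.sum((noiseless - noiseless.mean()) ** 2)
        assert r2 >= 0.98

    def test_dominance_on_recovery_set(self, rng):
        # proposed RMSE <= min(averaging, sensor-only) + 0.5 points and
        # upper bound <= proposed, on the planted-weights construction
        n, m = 200, 6
        X = 0.5 + 0.15 * rng.normal(size=(n, m))
        theta_true = np.array([0.3, 0.2, 0.15, 0.1, 0.05, 0.05])
        w = X @ theta_true
        y_c = 60 + 15 * rng.normal(size=n)
        y_s = y_c + 8 * rng.normal(size=n)
        y = w * y_c + (1 - w) * y_s + 0.5 * rng.normal(size=n)
        model = fit_fusion(FusionTrainingSet(X, y_c, y_s, y))
        w_fit = np.clip(X @ model.theta, 0, 1)
        proposed = w_fit * y_c + (1 - w_fit) * y_s
        ub, _ = upper_bound_select(y_c, y_s, y)
        rmse = lambda e: float(np.sqrt(np.mean((e - y) ** 2)))
        assert rmse(proposed) <= min(rmse(0.5 * y_c + 0.5 * y_s), rmse(y_s)) + 0.5
        # the oracle selection dominates any convex blend only where both
        # estimates err on the same side of the truth; there it holds
        # per subject by construction
        same_side = (y_c - y) * (y_s - y) > 0
        assert same_side.sum() > 5
        assert np.all(np.abs(ub - y)[same_side]
                      <= np.abs(proposed - y)[same_side] + 1e-9)


class TestPredict:
    def test_theta_zero_gives_sensor(self, rng):
        model = fit_fusion(_random_training(rng))
        model.theta = np.zeros(2)
        pred = fuse_predict(model, np.zeros(2), 70.0, 50.0)
        assert pred.omega_c == 0.0
        assert pred.fused == 50.0

    def test_weight_one_gives_clinical(self):
        scaler = Standardizer(np.zeros(2), np.ones(2))
        from rehabfuse.fusion import FusionModel
        model = FusionModel(np.array([1.0, 0.0]), scaler)
        pred = fuse_predict(model, np.array([1.0, 5.0]), 70.0, 50.0)
        assert pred.fused == 70.0

    def test_overweight_clipped(self):
        from rehabfuse.fusion import FusionModel
        model = FusionModel(np.array([1.4]), Standardizer(np.zeros(1), np.ones(1)))
        pred = fuse_predict(model, np.array([1.0]), 70.0, 50.0)
        assert pred.omega_c == 1.0

    def test_weights_sum_to_one(self, rng):
        model = fit_fusion(_random_training(rng))
        pred = fuse_predict(model, rng.normal(size=2), 70.0, 50.0)
        assert pred.omega_c + pred.omega_s == pytest.approx(1.0)


class TestBenchmarks:
    def test_averaging(self):
        assert averaging_weights(60.0, 80.0).fused == 70.0
        assert averaging_weights(55.0, 55.0).fused == 55.0
        p = averaging_weights(1.0, 2.0)
        assert p.omega_c + p.omega_s == 1.0

    def test_variance_as_printed(self):
        p = variance_weights(3.0, 1.0, 100.0, 0.0, convention="as_printed")
        assert p.omega_c == pytest.approx(0.75)

    def test_variance_conventions_complementary(self, rng):
        for _ in range(10):
            vc, vs = rng.uniform(0.1, 5, size=2)
            a = variance_weights(vc, vs, 0, 0, convention="as_printed")
            b = variance_weights(vc, vs, 0, 0, convention="inverse_variance")
            assert a.omega_c == pytest.approx(1.0 - b.omega_c)

    def test_equal_variances_give_half(self):
        for conv in ("as_printed", "inverse_variance"):
            assert variance_weights(2.0, 2.0, 0, 0, conv).omega_c == 0.5

    def test_zero_variances_warn_and_average(self):
        with pytest.warns(RuntimeWarning):
            p = variance_weights(0.0, 0.0, 10.0, 20.0)
        assert p.fused == 15.0

    def test_upper_bound_selection_and_ties(self):
        y = np.array([50.0, 50.0, 50.0])
        y_c = np.array([52.0, 49.0, 51.0])
        y_s = np.array([51.0, 52.0, 49.0])   # better, worse, tie
        sel, sensor_mask = upper_bound_select(y_c, y_s, y)
        assert sel.tolist() == [51.0, 49.0, 49.0]
        assert sensor_mask.tolist() == [True, False, True]
        err = np.abs(sel - y)
        assert np.all(err <= np.abs(y_c - y) + 1e-12)
        assert np.all(err <= np.abs(y_s - y) + 1e-12)
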