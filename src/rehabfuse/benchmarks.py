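"""Self-contained benchmark computations for validating the pipeline.

Each function recomputes one verifiable quantity from scratch — analytic
constants of the score mapping, solver-vs-oracle gaps, closed-form GP
errors, interval coverage, filter gains, selection recovery rates, and the
full LOSOCV cohort evaluation — so the package's behavior can be audited
end to end from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .estimators import (FAS_MAX_POINTS, GPRConfig, gpr_fit, gpr_predict,
                         total_fas_percent)
from .evaluation import error_vs_change, run_losocv
from .features import build_feature_tables, cfs_select
from .fusion import FusionTrainingSet, assemble_qp, averaging_weights, fit_fusion
from .synthgen import CohortConfig, generate_dataset
from .workflow import ExperimentConfig

__all__ = [
    "score_mapping_constants",
    "averaging_weight",
    "qp_grid_benchmark",
    "fusion_recovery_benchmark",
    "gpr_closed_form_error",
    "gpr_interval_coverage",
    "filter_gain_benchmark",
    "cfs_recovery_benchmark",
    "run_cohort_batch",
    "cohort_batch_summary",
]


# --------------------------------------------------------------------- scores

def score_mapping_constants() -> dict[str, float]:
    """Intercept/slope (points) and full-scale maximum of the total mapping."""
    pct0 = total_fas_percent(0.0)
    pct1 = total_fas_percent(1.0)
    intercept_points = pct0 / 100.0 * FAS_MAX_POINTS
    slope_points = (pct1 - pct0) / 100.0 * FAS_MAX_POINTS
    return {"intercept_points": intercept_points,
            "slope_points_per_unit": slope_points,
            "max_points": float(FAS_MAX_POINTS)}


def averaging_weight() -> float:
    """Clinical weight actually applied by the averaging combiner."""
    return averaging_weights(100.0, 0.0).fused / 100.0


# ------------------------------------------------------------------------- QP

def _grid_search_qp(qp, step: float = 1e-3, box: float = 3.0,
                    refine: bool = True) -> float:
    """Feasible-grid oracle for the fusion QP (m <= 2); returns min J."""
    m = qp.A.shape[1]
    if m == 1:
        lo, hi = -box, box
        for xi in qp.X_c[:, 0]:
            if xi > 0:
                lo, hi = max(lo, 0.0), min(hi, 1.0 / xi)
            elif xi < 0:
                lo, hi = max(lo, 1.0 / xi), min(hi, 0.0)
        grid = np.append(np.arange(lo, hi, step), hi)[:, None]
        J = [qp.objective(t) for t in grid]
        best_J, best_t = float(np.min(J)), grid[int(np.argmin(J))]
        if refine:
            fine = best_t[0] + np.arange(-step, step, 1e-5)
            fine = fine[(fine >= lo) & (fine <= hi)]
            if fine.size:
                Jf = [qp.objective(np.array([t])) for t in fine]
                best_J = min(best_J, float(np.min(Jf)))
        return best_J

    # m == 2: localize the feasible polygon coarsely, then grid at `step`
    coarse = np.arange(-box, box + 0.02, 0.02)
    T = np.array(np.meshgrid(coarse, coarse)).reshape(2, -1).T
    W = qp.X_c @ T.T
    ok = ((W >= -1e-9) & (W <= 1 + 1e-9)).all(axis=0)
    pts = T[ok]
    if pts.size == 0:
        return 0.0
    lo = pts.min(axis=0) - 0.05
    hi = pts.max(axis=0) + 0.05
    P = qp.A.T @ qp.A
    q2 = qp.b @ qp.A

    def scan(g0, g1):
        best = (np.inf, None)
        for chunk in np.array_split(g0, max(1, g0.size // 400)):
            T = np.array(np.meshgrid(chunk, g1)).reshape(2, -1).T
            W = qp.X_c @ T.T
            ok = ((W >= 0) & (W <= 1)).all(axis=0)
            if not ok.any():
                continue
            Tf = T[ok]
            J = np.einsum("ij,jk,ik->i", Tf, P, Tf) - 2.0 * q2 @ Tf.T
            i = int(np.argmin(J))
            if J[i] < best[0]:
                best = (float(J[i]), Tf[i])
        return best

    J_best, t_best = scan(np.arange(lo[0], hi[0] + step, step),
                          np.arange(lo[1], hi[1] + step, step))
    if refine and t_best is not None:
        J_fine, _ = scan(t_best[0] + np.arange(-step, step, 1e-5),
                         t_best[1] + np.arange(-step, step, 1e-5))
        J_best = min(J_best, J_fine)
    return J_best


def qp_grid_benchmark(seed: int, n_instances: int = 100) -> dict[str, float]:
    """Solver-vs-grid-oracle comparison on random fusion instances.

    Half the instances have one clinical covariate, half two. Reports the
    worst signed objective gap ``J(theta*) - J(grid)`` (negative means the
    solver beat the finite grid, as it should) and the worst constraint
    violation at theta*.
    """
    rng = np.random.default_rng(seed)
    worst_gap = -np.inf
    worst_viol = 0.0
    for i in range(n_instances):
        m = 1 if i < n_instances // 2 else 2
        n = int(rng.integers(5, 12))
        X = 0.5 + 0.4 * rng.normal(size=(n, m))
        y_c = 60 + 10 * rng.normal(size=n)
        y_s = y_c + 6 * rng.normal(size=n)
        y = 0.5 * (y_c + y_s) + rng.normal(size=n)
        tr = FusionTrainingSet(X, y_c, y_s, y)
        qp = assemble_qp(tr)
        model = fit_fusion(tr, ridge=0.0)
        J_star = qp.objective(model.theta)
        J_grid = _grid_search_qp(qp)
        worst_gap = max(worst_gap, J_star - J_grid)
        worst_viol = max(worst_viol, qp.constraint_violation(model.theta))
    return {"max_objective_gap": worst_gap, "max_constraint_violation": worst_viol,
            "n_instances": n_instances}


def fusion_recovery_benchmark(seed: int, n: int = 200, m: int = 6,
                              noise_sd: float = 0.5) -> dict[str, float]:
    """Planted-weights recovery: R^2 of fitted vs noiseless fused values."""
    rng = np.random.default_rng(seed)
    X = 0.5 + 0.15 * rng.normal(size=(n, m))
    theta_true = np.array([0.3, 0.2, 0.15, 0.1, 0.05, 0.05])[:m]
    w = X @ theta_true
    assert w.min() >= 0.0 and w.max() <= 1.0
    y_c = 60 + 15 * rng.normal(size=n)
    y_s = y_c + 8 * rng.normal(size=n)
    noiseless = w * y_c + (1 - w) * y_s
    y = noiseless + noise_sd * rng.normal(size=n)
    model = fit_fusion(FusionTrainingSet(X, y_c, y_s, y))
    w_fit = np.clip(X @ model.theta, 0.0, 1.0)
    fitted = w_fit * y_c + (1 - w_fit) * y_s
    r2 = 1.0 - np.sum((fitted - noiseless) ** 2) / \
        np.sum((noiseless - noiseless.mean()) ** 2)
    return {"r2": float(r2), "n": n}


# ------------------------------------------------------------------------ GPR

def gpr_closed_form_error() -> float:
    """Max |error| of the posterior vs the hand-computed 2-point formulas."""
    X = np.array([[0.0], [1.0]])
    y = np.array([1.0, 2.0])
    cfg = GPRConfig(optimize=False, sigma_f=1.5, length_scale=0.8, sigma_n=0.3,
                    jitter=0.0, include_noise_in_variance=False)
    model = gpr_fit(X, y, cfg)
    xs = np.linspace(-1.0, 2.0, 7)[:, None]
    k = lambda a, b: 1.5**2 * np.exp(-0.5 * (a - b) ** 2 / 0.8**2)
    K = np.array([[k(0, 0) + 0.09, k(0, 1)], [k(1, 0), k(1, 1) + 0.09]])
    err = 0.0
    for x in xs.ravel():
        ks = np.array([k(0.0, x), k(1.0, x)])
        mean_cf = y.mean() + ks @ np.linalg.solve(K, y - y.mean())
        var_cf = k(x, x) - ks @ np.linalg.solve(K, ks)
        mu, var = gpr_predict(model, [[x]])
        err = max(err, abs(mu[0] - mean_cf), abs(var[0] - var_cf))
    return float(err)


def gpr_interval_coverage(seed: int, n_seeds: int = 10, n_train: int = 100,
                          n_test: int = 100) -> dict[str, float]:
    """Empirical coverage of 95% predictive intervals on synthetic GP draws."""
    ell, sf, sn = 1.0, 2.0, 0.3
    hits = total = 0
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in base:
        rng = np.random.default_rng(int(s))
        X = rng.uniform(-3, 3, size=(n_train + n_test, 1))
        d = (X - X.T) ** 2
        K = sf**2 * np.exp(-0.5 * d / ell**2)
        f = rng.multivariate_normal(np.zeros(len(X)), K + 1e-10 * np.eye(len(X)))
        y = f + sn * rng.normal(size=len(X))
        model = gpr_fit(X[:n_train], y[:n_train], seed=int(s))
        mu, var = gpr_predict(model, X[n_train:])
        half = 1.959963984540054 * np.sqrt(var)
        hits += int(np.sum(np.abs(y[n_train:] - mu) <= half))
        total += n_test
    return {"coverage_pct": 100.0 * hits / total, "n": total}


# --------------------------------------------------------------------- signal

def filter_gain_benchmark() -> dict[str, float]:
    """Steady-state gain of the implemented low-pass vs its design response.

    A 20 Hz sinusoid at 51.2 Hz through the zero-phase 6th-order 8 Hz
    Butterworth filter must come out with amplitude |H(20)|^2 (the
    forward-backward pass squares the magnitude response). Also reports the
    worst-case error of the raw trapezoid integral of a constant
    acceleration against the exact linear ramp.
    """
    from .signal import TimeSeries, butterworth_filter, trapezoid_integral

    fs, f0 = 51.2, 20.0
    t = np.arange(int(60 * fs)) / fs
    x = np.sin(2 * np.pi * f0 * t)
    out = butterworth_filter(TimeSeries(x, fs), "lowpass", 6, 8.0).values
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    amp = 2.0 * np.hypot(np.mean(out[mid] * np.cos(2 * np.pi * f0 * t[mid])),
                         np.mean(out[mid] * np.sin(2 * np.pi * f0 * t[mid])))
    sos = sps.butter(6, 8.0, "lowpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
    designed = float(np.abs(h[0]) ** 2)
    gain_rel_err = abs(amp - designed) / designed

    n = int(2 * fs) + 1
    ramp = trapezoid_integral(TimeSeries(np.ones(n), fs)).values
    trap_err = float(np.max(np.abs(ramp - np.arange(n) / fs)))
    return {"gain_rel_err": float(gain_rel_err), "measured_gain": float(amp),
            "designed_gain": designed, "trapezoid_max_err": trap_err}


# ------------------------------------------------------------------------ CFS

def cfs_recovery_benchmark(seed: int, n_trials: int = 100) -> dict[str, float]:
    """Planted-feature recovery and best-first vs exhaustive merit ratio."""
    rng = np.random.default_rng(seed)
    recovered = 0
    worst_ratio = np.inf
    for _ in range(n_trials):
        p = int(rng.integers(6, 13))
        n = int(rng.integers(30, 60))
        X = rng.normal(size=(n, p))
        informative = int(rng.integers(0, p))
        y = X[:, informative] + 0.05 * rng.normal(size=n)
        bf = cfs_select(X, y)
        ex = cfs_select(X, y, search="exhaustive")
        if bf.subset == [f"f{informative}"]:
            recovered += 1
        if ex.merit > 0:
            worst_ratio = min(worst_ratio, bf.merit / ex.merit)
    return {"recovery_rate_pct": 100.0 * recovered / n_trials,
            "min_merit_ratio": float(worst_ratio), "n_trials": n_trials}


# --------------------------------------------------------------------- cohort

@dataclass
class CohortRunResult:
    seed: int
    rmse: dict[str, float]
    ordering_holds: bool
    clinical_slope: dict[str, float]
    sensor_slope: dict[str, float]
    summary: "object"
    report: "object"


def run_cohort_batch(seeds: list[int]) -> list[CohortRunResult]:
    """Full default-cohort LOSOCV evaluation for each seed.

    Each run simulates the default n=40 cohort (8 tasks x 3 repetitions x
    2 visits), extracts features, and evaluates all six methods by
    leave-one-subject-out cross-validation.
    """
    results = []
    for seed in seeds:
        cfg = ExperimentConfig(seed=int(seed))
        dataset = generate_dataset(cfg.cohort, cfg.recording, seed=int(seed),
                                   n_repetitions=cfg.n_repetitions)
        tables = build_feature_tables(dataset, cfg.registry)
        report = run_losocv(dataset, tables, cfg.losocv, seed=int(seed))
        summary = report.summary()
        rmse = summary["rmse"].to_dict()
        ordering = (rmse["upper_bound"] <= rmse["proposed"] + 1e-9
                    and rmse["proposed"] <= rmse["sensor"] + 1e-9
                    and rmse["sensor"] <= rmse["clinical"] + 1e-9)
        change = report.predictions["change_true"].to_numpy()
        results.append(CohortRunResult(
            seed=int(seed), rmse=rmse, ordering_holds=bool(ordering),
            clinical_slope=error_vs_change(report.errors("clinical"), change),
            sensor_slope=error_vs_change(report.errors("sensor"), change),
            summary=summary, report=report))
    return results


def cohort_batch_summary(results: list[CohortRunResult]) -> dict[str, float]:
    """Aggregate the batch into the quantities the benchmarks track."""
    n5 = min(5, len(results))
    ordering_frac_5 = float(np.mean([r.ordering_holds for r in results[:n5]]))
    clin_sig_neg = [r.clinical_slope["p"] < 0.05 and r.clinical_slope["slope"] < 0
                    for r in results]
    sens_cover0 = [r.sensor_slope["slope_ci_low"] <= 0 <= r.sensor_slope["slope_ci_high"]
                   for r in results]
    out = {
        "ordering_fraction_first5": ordering_frac_5,
        "clinical_slope_sig_negative_fraction": float(np.mean(clin_sig_neg)),
        "sensor_slope_ci_covers_zero_fraction": float(np.mean(sens_cover0)),
        "mean_clinical_slope": float(np.mean([r.clinical_slope["slope"]
                                              for r in results])),
        "mean_sensor_slope": float(np.mean([r.sensor_slope["slope"]
                                            for r in results])),
        "n_seeds": len(results),
    }
    for method in ("sensor", "clinical", "averaging", "variance",
                   "upper_bound", "proposed"):
        out[f"mean_rmse_{method}"] = float(np.mean([r.rmse[method]
                                                    for r in results]))
    return out
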