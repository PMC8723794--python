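"""Covariate-conditioned constrained linear fusion of two FAS estimators.

The fused post-treatment score is a convex combination of the clinical
estimate and the sensor estimate,

    y_hat = w_c * y_hat_c + (1 - w_c) * y_hat_s,      0 <= w_c <= 1,

where the clinical weight is a linear function of the subject's normalized
clinical covariates, ``w_c,i = x_c,i @ theta``. Over a training set of n
subjects the residual can be written with ``A = X_c ∘ (y_hat_c - y_hat_s)``
(each covariate row scaled by the estimate gap) and ``b = y - y_hat_s``, so
the training objective is the convex quadratic

    J(theta) = theta^T A^T A theta - 2 b^T A theta  =  ||b - A theta||^2 - ||b||^2,

minimized subject to the elementwise box constraint ``0 <= X_c theta <= 1``
(theta = 0 is always feasible). This module assembles and solves that QP
and also provides the three benchmark combiners: equal-weight averaging,
predictive-variance weighting (both the formula as printed in the source
convention and its inverse-variance counterpart), and the per-subject
oracle "upper bound" that picks whichever estimate is closer to the
clinician score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .estimators import Standardizer

__all__ = [
    "FusionTrainingSet",
    "QPProblem",
    "FusionModel",
    "WeightedPrediction",
    "assemble_qp",
    "fit_fusion",
    "fuse_predict",
    "averaging_weights",
    "variance_weights",
    "upper_bound_select",
]


@dataclass
class FusionTrainingSet:
    """Training data for the fusion weights.

    ``X_c``: n x m clinical covariates normalized to zero mean / unit
    variance on the training rows; ``y_c`` / ``y_s``: clinical and sensor
    estimates of the post-treatment total FAS [%]; ``y``: clinician scores.
    """

    X_c: np.ndarray
    y_c: np.ndarray
    y_s: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X_c = np.atleast_2d(np.asarray(self.X_c, float))
        self.y_c = np.asarray(self.y_c, float).ravel()
        self.y_s = np.asarray(self.y_s, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        n = self.X_c.shape[0]
        if not (self.y_c.size == self.y_s.size == self.y.size == n):
            raise ValueError("X_c, y_c, y_s and y must have matching lengths")

    @property
    def n(self) -> int:
        return self.X_c.shape[0]

    @property
    def m(self) -> int:
        return self.X_c.shape[1]


@dataclass
class QPProblem:
    """The assembled quadratic program ``min J(theta) s.t. 0 <= X_c theta <= 1``."""

    A: np.ndarray
    b: np.ndarray
    X_c: np.ndarray

    def objective(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, float).ravel()
        return float(theta @ (self.A.T @ self.A) @ theta
                     - 2.0 * (self.b @ self.A) @ theta)

    def residual_norm_sq(self, theta: np.ndarray) -> float:
        r = self.b - self.A @ np.asarray(theta, float).ravel()
        return float(r @ r)

    def constraint_violation(self, theta: np.ndarray) -> float:
        w = self.X_c @ np.asarray(theta, float).ravel()
        return float(max(np.max(-w, initial=0.0), np.max(w - 1.0, initial=0.0)))


@dataclass
class WeightedPrediction:
    """A convex combination of the two estimates."""

    omega_c: float
    fused: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega_c <= 1.0:
            raise ValueError(f"omega_c must lie in [0, 1], got {self.omega_c}")

    @property
    def omega_s(self) -> float:
        return 1.0 - self.omega_c


@dataclass
class FusionModel:
    """Fitted fusion weights and the covariate normalization that defines them."""

    theta: np.ndarray
    standardizer: Standardizer
    clip_test_weights: bool = True
    objective: float = 0.0
    constraint_violation: float = 0.0
    solver_status: str = ""
    include_intercept: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "theta": self.theta.tolist(),
            "mean": self.standardizer.mean.tolist(),
            "sd": self.standardizer.sd.tolist(),
            "clip_test_weights": self.clip_test_weights,
            "objective": self.objective,
            "constraint_violation": self.constraint_violation,
            "solver_status": self.solver_status,
            "include_intercept": self.include_intercept,
        })

    @classmethod
    def from_json(cls, text: str) -> "FusionModel":
        d = json.loads(text)
        return cls(np.asarray(d["theta"], float),
                   Standardizer(np.asarray(d["mean"], float), np.asarray(d["sd"], float)),
                   d["clip_test_weights"], d["objective"],
                   d["constraint_violation"], d["solver_status"],
                   d["include_intercept"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        return cls.from_json(Path(path).read_text())


def assemble_qp(training: FusionTrainingSet) -> QPProblem:
    """Assemble ``A = X_c`` row-scaled by the estimate gap and ``b = y - y_s``."""
    if training.n == 0:
        raise ValueError("cannot assemble a QP from an empty training set")
    gap = training.y_c - training.y_s
    A = training.X_c * gap[:, None]
    b = training.y - training.y_s
    return QPProblem(A, b, training.X_c)


def _solve_qp(qp: QPProblem, ridge: float, tol: float) -> tuple[np.ndarray, str]:
    m = qp.A.shape[1]
    P = qp.A.T @ qp.A + ridge * np.eye(m)
    q = qp.A.T @ qp.b

    def fun(th):
        return float(th @ P @ th - 2.0 * q @ th)

    def jac(th):
        return 2.0 * (P @ th - q)

    def hess(_):
        return 2.0 * P

    constraint = LinearConstraint(qp.X_c, 0.0, 1.0)
    res = minimize(fun, np.zeros(m), jac=jac, hess=hess, method="trust-constr",
                   constraints=[constraint],
                   options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 500,
                            "barrier_tol": 1e-12})
    theta = np.asarray(res.x, float)
    theta = _active_set_polish(qp, P, q, theta)
    # interior-point iterates can sit a hair outside the box; shrinking
    # toward the always-feasible theta = 0 restores feasibility
    viol = qp.constraint_violation(theta)
    if viol > tol:
        w = qp.X_c @ theta
        scale = 1.0
        if w.max(initial=0.0) > 1.0:
            scale = min(scale, 1.0 / w.max())
        if w.min(initial=0.0) < 0.0:
            # scaling toward zero shrinks negative violations proportionally
            scale = min(scale, tol / max(-w.min(), tol))
        theta = theta * scale
        viol = qp.constraint_violation(theta)
    if not res.success and viol > 1e-6:
        raise RuntimeError(
            f"QP solver failed: {res.message}; constraint violation {viol:.2e}")
    # theta = 0 is always feasible; never return anything worse
    if qp.objective(theta) > 0.0:
        theta = np.zeros(m)
    return theta, str(res.status)


def _active_set_polish(qp: QPProblem, P: np.ndarray, q: np.ndarray,
                       theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Refine an interior-point solution on its active constraint set.

    The barrier method stops a hair away from active box faces; solving the
    equality-constrained KKT system on the near-active rows of ``X_c``
    recovers the exact constrained optimum. The refined point is accepted
    only if it is feasible and improves the objective.
    """
    w = qp.X_c @ theta
    rows, vals = [], []
    for i, wi in enumerate(w):
        if wi <= eps:
            rows.append(i); vals.append(0.0)
        elif wi >= 1.0 - eps:
            rows.append(i); vals.append(1.0)
    m = theta.size
    if rows:
        C = qp.X_c[rows]
        d = np.asarray(vals)
        k = C.shape[0]
        kkt = np.block([[2.0 * P, C.T], [C, np.zeros((k, k))]])
        rhs = np.concatenate([2.0 * q, d])
    else:
        kkt, rhs = 2.0 * P, 2.0 * q
    try:
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return theta
    cand = sol[:m]
    if qp.constraint_violation(cand) <= 1e-10 and \
            qp.objective(cand) < qp.objective(theta):
        return cand
    return theta


def fit_fusion(training: FusionTrainingSet, ridge: float = 1e-8,
               constraint_tol: float = 1e-8,
               clip_test_weights: bool = True,
               standardizer: Standardizer | None = None) -> FusionModel:
    """Fit the fusion weights by constrained quadratic programming.

    ``training.X_c`` must already be normalized; pass the fitted
    ``standardizer`` so test covariates can be normalized with the same
    training statistics. A tiny ridge keeps ``A^T A`` positive definite
    when the estimate gaps are degenerate.
    """
    qp = assemble_qp(training)
    theta, status = _solve_qp(qp, ridge, constraint_tol)
    if standardizer is None:
        standardizer = Standardizer(np.zeros(training.m), np.ones(training.m))
    return FusionModel(theta, standardizer, clip_test_weights,
                       objective=qp.objective(theta),
                       constraint_violation=qp.constraint_violation(theta),
                       solver_status=status)


def fuse_predict(model: FusionModel, covariates_raw: np.ndarray,
                 y_c: float, y_s: float) -> WeightedPrediction:
    """Fused prediction for one subject from raw (unnormalized) covariates.

    The clinical weight is ``w_c = x_c' theta`` with the covariates
    normalized by the model's training statistics; test-time weights are
    clipped to [0, 1] (the training constraint binds only training rows).
    """
    covariates_raw = np.asarray(covariates_raw, float).ravel()
    if covariates_raw.size != model.standardizer.mean.size:
        raise ValueError(
            f"expected {model.standardizer.mean.size} covariates, "
            f"got {covariates_raw.size}")
    if not np.all(np.isfinite(covariates_raw)):
        raise ValueError("covariates must be finite (no missing values)")
    x = model.standardizer.transform(covariates_raw[None, :]).ravel()
    w = float(x @ model.theta)
    if model.clip_test_weights:
        w = float(np.clip(w, 0.0, 1.0))
    elif not 0.0 <= w <= 1.0:
        raise ValueError(f"unclipped test weight {w} outside [0, 1]")
    return WeightedPrediction(w, w * y_c + (1.0 - w) * y_s)


def averaging_weights(y_c: float, y_s: float) -> WeightedPrediction:
    """Equal-weight benchmark: ``w_c = 0.5``."""
    return WeightedPrediction(0.5, 0.5 * y_c + 0.5 * y_s)


def variance_weights(V_c: float, V_s: float, y_c: float, y_s: float,
                     convention: Literal["as_printed", "inverse_variance"]
                     = "as_printed") -> WeightedPrediction:
    """Predictive-variance-based weighting benchmark.

    ``as_printed`` uses ``w_c = V_c / (V_c + V_s)`` — the formula exactly
    as published, which up-weights the *more* uncertain estimate.
    ``inverse_variance`` uses ``w_c = V_s / (V_c + V_s)``, the standard
    precision weighting. Both are provided because the printed form is
    plausibly a typo; the default stays faithful to the text.
    """
    if V_c < 0 or V_s < 0:
        raise ValueError("predictive variances must be non-negative")
    total = V_c + V_s
    if total == 0.0:
        import warnings
        warnings.warn("both predictive variances are zero; falling back to "
                      "equal weights", RuntimeWarning, stacklevel=2)
        w = 0.5
    elif convention == "as_printed":
        w = V_c / total
    elif convention == "inverse_variance":
        w = V_s / total
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return WeightedPrediction(float(w), float(w * y_c + (1.0 - w) * y_s))


def upper_bound_select(y_c: np.ndarray, y_s: np.ndarray,
                       y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Oracle benchmark: per subject, the estimate with smaller absolute error.

    Requires the true scores, so it is a diagnostic bound rather than a
    usable predictor. Ties go to the sensor estimate. Returns
    ``(selected_estimates, chose_sensor_mask)``.
    """
    y_c = np.asarray(y_c, float).ravel()
    y_s = np.asarray(y_s, float).ravel()
    y = np.asarray(y, float).ravel()
    sensor_better = np.abs(y_s - y) <= np.abs(y_c - y)
    return np.where(sensor_better, y_s, y_c), sensor_better
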