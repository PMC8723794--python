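"""Gaussian process regression and the task-to-total FAS score mapping.

Two GPR models drive the pipeline: a per-task model mapping kinematic
features of a task repetition to its 0-5 FAS score, and a clinical model
mapping six baseline covariates to the change in total FAS between visits.
Both use the squared-exponential (RBF) covariance

    k(x, x') = sigma_f^2 exp(-||x - x'||^2 / (2 l^2))

with an isotropic length-scale on standardized inputs, additive Gaussian
observation noise sigma_n^2, and hyperparameters fitted by MAP: the log
marginal likelihood plus weak log-normal hyperpriors, maximized from
multiple starts. MAP (rather than plain maximum likelihood) regularizes
hyperparameters on the small training sets typical of this setting; a
config switch disables the priors.

The module also carries the eight-task-to-total mapping: the mean 0-5
scores of the eight tasks are summed to ``FAS_8Tasks`` and mapped to total
FAS points as ``FAS_8Tasks * 1.78 + 2.97``, then expressed as a percentage
of the 75-point full scale (15 tasks x 5 points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize

__all__ = [
    "FAS_SLOPE",
    "FAS_INTERCEPT",
    "FAS_MAX_POINTS",
    "GPRConfig",
    "GPRModel",
    "PredictiveEstimate",
    "TaskScoreSet",
    "gpr_fit",
    "gpr_predict",
    "loo_block_predict",
    "estimate_task_scores",
    "total_fas_percent",
    "invert_total_fas_percent",
    "clinical_post_estimate",
    "Standardizer",
]

#: linear mapping from the eight-task combined score to total FAS points
FAS_SLOPE = 1.78
FAS_INTERCEPT = 2.97
#: maximum attainable total FAS points (15 tasks x 5 points)
FAS_MAX_POINTS = 75.0


@dataclass
class GPRConfig:
    """Hyperparameter-fitting settings for the RBF Gaussian process."""

    optimize: bool = True
    use_priors: bool = True          # MAP (True) vs plain marginal likelihood
    prior_sd: float = 2.0            # SD of the log-normal hyperpriors
    n_restarts: int = 1              # additional perturbed starts beyond the heuristic
    maxiter: int = 60
    jitter: float = 1e-10
    max_jitter: float = 1e-6
    include_noise_in_variance: bool = True
    # fixed hyperparameters used when optimize=False
    sigma_f: float = 1.0
    length_scale: float = 1.0
    sigma_n: float = 0.1


@dataclass
class PredictiveEstimate:
    """Posterior predictive mean and variance in target units."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < -1e-12:
            raise ValueError("predictive variance must be non-negative")
        self.variance = max(self.variance, 0.0)


@dataclass
class GPRModel:
    """A fitted RBF Gaussian process (training data + hyperparameters)."""

    X: np.ndarray
    y: np.ndarray
    sigma_f: float
    length_scale: float
    sigma_n: float
    y_mean: float = 0.0
    jitter: float = 1e-10
    include_noise_in_variance: bool = True
    L: np.ndarray = field(default=None, repr=False)       # chol(K + sigma_n^2 I)
    alpha: np.ndarray = field(default=None, repr=False)   # (K + sigma_n^2 I)^-1 (y - mean)
    _K_inv: np.ndarray = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    def kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return _rbf(A, B, self.sigma_f, self.length_scale)

    def K_inv(self) -> np.ndarray:
        if self._K_inv is None:
            eye = np.eye(self.n_train)
            self._K_inv = sla.cho_solve((self.L, True), eye)
        return self._K_inv

    def to_json(self) -> str:
        return json.dumps({
            "sigma_f": self.sigma_f, "length_scale": self.length_scale,
            "sigma_n": self.sigma_n, "y_mean": self.y_mean,
            "jitter": self.jitter,
            "include_noise_in_variance": self.include_noise_in_variance,
            "X": self.X.tolist(), "y": self.y.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "GPRModel":
        d = json.loads(text)
        model = cls(np.asarray(d["X"], float), np.asarray(d["y"], float),
                    d["sigma_f"], d["length_scale"], d["sigma_n"],
                    y_mean=d["y_mean"], jitter=d["jitter"],
                    include_noise_in_variance=d["include_noise_in_variance"])
        _factorize(model)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GPRModel":
        return cls.from_json(Path(path).read_text())


def _rbf(A: np.ndarray, B: np.ndarray, sigma_f: float, ell: float) -> np.ndarray:
    a2 = (A**2).sum(axis=1)[:, None]
    b2 = (B**2).sum(axis=1)[None, :]
    sq = np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)
    return sigma_f**2 * np.exp(-0.5 * sq / ell**2)


def _factorize(model: GPRModel) -> None:
    n = model.n_train
    K = model.kernel(model.X, model.X)
    jitter = model.jitter
    while True:
        try:
            model.L = sla.cholesky(K + (model.sigma_n**2 + jitter) * np.eye(n),
                                   lower=True)
            break
        except sla.LinAlgError:
            jitter *= 100.0
            if jitter > 1e-4:
                raise RuntimeError(
                    "kernel matrix is singular even after jitter escalation")
    model.jitter = jitter
    model.alpha = sla.cho_solve((model.L, True), model.y - model.y_mean)
    model._K_inv = None


def _neg_log_posterior(phi: np.ndarray, X: np.ndarray, yc: np.ndarray,
                       config: GPRConfig, phi0: np.ndarray):
    """Negative log marginal likelihood (+ hyperprior) and its gradient.

    ``phi = (log sigma_f, log ell, log sigma_n)``, ``yc`` mean-centered.
    """
    n = X.shape[0]
    sf, ell, sn = np.exp(phi)
    Kf = _rbf(X, X, 1.0, ell)          # unit-signal kernel
    K = sf**2 * Kf
    Ky = K + (sn**2 + config.jitter) * np.eye(n)
    try:
        L = sla.cholesky(Ky, lower=True)
    except sla.LinAlgError:
        return 1e10, np.zeros(3)
    alpha = sla.cho_solve((L, True), yc)
    nll = 0.5 * yc @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)

    Kinv = sla.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv       # d nll/d K = -W/2
    # dK/d log sf = 2 K ; dK/d log ell = K * sq/ell^2 ; dK/d log sn = 2 sn^2 I
    sq = -2.0 * ell**2 * np.log(np.maximum(Kf, 1e-300))
    g_sf = -0.5 * np.sum(W * (2.0 * K))
    g_ell = -0.5 * np.sum(W * (K * (sq / ell**2)))
    g_sn = -0.5 * np.trace(W) * 2.0 * sn**2
    grad = np.array([g_sf, g_ell, g_sn])

    if config.use_priors:
        nll += 0.5 * ((phi - phi0) ** 2).sum() / config.prior_sd**2
        grad = grad + (phi - phi0) / config.prior_sd**2
    return nll, grad


def gpr_fit(X: np.ndarray, y: np.ndarray, config: GPRConfig | None = None,
            seed: int | None = None) -> GPRModel:
    """Fit an RBF Gaussian process to ``(X, y)``.

    Inputs are expected already standardized on training statistics (see
    :class:`Standardizer`). Targets are mean-centered internally, so the
    prior mean equals the training mean. Deterministic given ``seed``.
    """
    config = config or GPRConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("at least 2 training rows are required")
    y_mean = float(y.mean())
    yc = y - y_mean
    sy = float(yc.std())

    if not config.optimize:
        model = GPRModel(X, y, config.sigma_f, config.length_scale, config.sigma_n,
                         y_mean=y_mean, jitter=config.jitter,
                         include_noise_in_variance=config.include_noise_in_variance)
        _factorize(model)
        return model

    if sy < 1e-12:
        # degenerate constant target: predict the constant everywhere
        model = GPRModel(X, y, 1e-6, 1.0, 1e-6, y_mean=y_mean,
                         jitter=config.jitter,
                         include_noise_in_variance=config.include_noise_in_variance)
        _factorize(model)
        return model

    # heuristic start: signal SD = target SD, length-scale = median distance,
    # noise = 10% of target SD; hyperpriors are centered here
    d2 = (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T
    med = np.sqrt(np.maximum(np.median(d2[np.triu_indices_from(d2, 1)]), 1e-6)) \
        if X.shape[0] > 1 else 1.0
    phi0 = np.log([sy, max(med, 1e-3), 0.1 * sy])

    rng = np.random.default_rng(seed)
    starts = [phi0] + [phi0 + rng.normal(0, 0.5, 3) for _ in range(config.n_restarts)]
    best, best_val = None, np.inf
    bounds = [(np.log(sy * 1e-4), np.log(sy * 1e3)),
              (np.log(1e-3), np.log(1e4)),
              (np.log(sy * 1e-5), np.log(sy * 1e2))]
    for start in starts:
        res = minimize(_neg_log_posterior, start, args=(X, yc, config, phi0),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": config.maxiter})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    sf, ell, sn = np.exp(best)
    model = GPRModel(X, y, float(sf), float(ell), float(sn), y_mean=y_mean,
                     jitter=config.jitter,
                     include_noise_in_variance=config.include_noise_in_variance)
    _factorize(model)
    return model


def gpr_predict(model: GPRModel, X_star: np.ndarray,
                full_cov: bool = False):
    """Posterior predictive means and variances at ``X_star``.

    Standard GP predictive equations: mean ``m + k*^T alpha`` and
    covariance ``k** - k*^T K_y^-1 k*`` (+ noise variance when the model
    was configured to include it). Returns ``(mean, var)`` arrays, or
    ``(mean, cov)`` with ``full_cov=True``.
    """
    X_star = np.atleast_2d(np.asarray(X_star, float))
    if X_star.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"X_star has {X_star.shape[1]} columns, model expects {model.X.shape[1]}")
    Ks = model.kernel(model.X, X_star)
    mean = model.y_mean + Ks.T @ model.alpha
    V = sla.solve_triangular(model.L, Ks, lower=True)
    noise = model.sigma_n**2 if model.include_noise_in_variance else 0.0
    if full_cov:
        Kss = model.kernel(X_star, X_star)
        cov = Kss - V.T @ V + noise * np.eye(X_star.shape[0])
        return mean, cov
    var = model.sigma_f**2 - (V**2).sum(axis=0) + noise
    return mean, np.maximum(var, 0.0)


def loo_block_predict(model: GPRModel, blocks: list[np.ndarray]):
    """Exact leave-block-out posterior predictions at the training rows.

    For each index block ``B`` this returns the posterior of ``y_B`` given
    all *other* training rows, computed from the closed-form identities

        mu_B  = y_B - (K_y^-1)_BB^-1 (K_y^-1 (y - m))_B
        Cov_B = (K_y^-1)_BB^-1

    (the block generalization of the standard GP leave-one-out formulas).
    The covariance includes the observation-noise term, i.e. it predicts
    noisy held-out observations. Hyperparameters stay at their full-fit
    values, so this is the exact inner leave-one-out posterior given the
    fitted model.
    """
    Kinv = model.K_inv()
    a = Kinv @ (model.y - model.y_mean)
    means, covs = [], []
    for B in blocks:
        B = np.asarray(B, int)
        sub = Kinv[np.ix_(B, B)]
        cov = sla.inv(sub)
        mu = model.y[B] - cov @ a[B]
        means.append(mu)
        covs.append(cov)
    return means, covs


@dataclass
class TaskScoreSet:
    """Per-task mean 0-5 scores and their total-FAS mapping."""

    task_scores: np.ndarray                  # 8 values in [0, 5]
    task_variances: np.ndarray | None = None  # variance of each task mean

    def __post_init__(self) -> None:
        self.task_scores = np.clip(np.asarray(self.task_scores, float), 0.0, 5.0)
        if self.task_variances is not None:
            self.task_variances = np.asarray(self.task_variances, float)

    @property
    def fas_8tasks(self) -> float:
        return float(self.task_scores.sum())

    @property
    def fas_total_pct(self) -> float:
        return total_fas_percent(self.fas_8tasks)

    @property
    def fas_total_pct_variance(self) -> float | None:
        """Variance of the total percentage, propagated through the mapping."""
        if self.task_variances is None:
            return None
        scale = FAS_SLOPE / FAS_MAX_POINTS * 100.0
        return float(self.task_variances.sum() * scale**2)


def estimate_task_scores(predictions: dict[str, np.ndarray],
                         variances: dict[str, np.ndarray] | None = None,
                         task_order: tuple[str, ...] | None = None) -> TaskScoreSet:
    """Average repetition-level score predictions into a task score set.

    ``predictions`` maps task id -> per-repetition predicted scores (any
    number >= 1 of repetitions); each task score is the mean of its
    repetitions clipped to [0, 5]. ``variances`` optionally maps task id ->
    the full covariance matrix (or per-repetition variances) of those
    predictions, propagated to the variance of the task mean.
    """
    from .synthgen import TASK_IDS  # canonical order; avoids circular import at load

    order = task_order or TASK_IDS
    scores, task_vars = [], []
    for task in order:
        if task not in predictions or len(np.atleast_1d(predictions[task])) == 0:
            raise ValueError(f"task {task!r} has no repetition predictions")
        reps = np.atleast_1d(np.asarray(predictions[task], float))
        scores.append(reps.mean())
        if variances is not None:
            v = np.asarray(variances[task], float)
            m = reps.size
            task_vars.append(v.sum() / m**2 if v.ndim == 2 else np.sum(v) / m**2)
    return TaskScoreSet(np.array(scores),
                        np.array(task_vars) if variances is not None else None)


def total_fas_percent(fas_8tasks: float) -> float:
    """Map the eight-task combined score to the total FAS percentage.

    Total points = ``FAS_8Tasks * 1.78 + 2.97``, expressed as a percentage
    of the 75-point full scale and clipped to [0, 100].
    """
    if not 0.0 <= fas_8tasks <= 40.0:
        raise ValueError(f"FAS_8Tasks must lie in [0, 40], got {fas_8tasks}")
    points = fas_8tasks * FAS_SLOPE + FAS_INTERCEPT
    return float(np.clip(points / FAS_MAX_POINTS * 100.0, 0.0, 100.0))


def invert_total_fas_percent(pct: float) -> float:
    """Inverse of :func:`total_fas_percent`, clipped to the valid domain."""
    points = pct / 100.0 * FAS_MAX_POINTS
    return float(np.clip((points - FAS_INTERCEPT) / FAS_SLOPE, 0.0, 40.0))


def clinical_post_estimate(covariates: np.ndarray, baseline_fas_pct: float,
                           model: GPRModel,
                           standardizer: "Standardizer") -> PredictiveEstimate:
    """Post-treatment total FAS estimate from the six clinical covariates.

    The GPR model predicts the *change* in total FAS between visits; the
    estimate adds that change to the baseline FAS, and the variance is the
    predictive variance of the change.
    """
    covariates = np.asarray(covariates, float).ravel()
    if covariates.size != standardizer.mean.size:
        raise ValueError(
            f"expected {standardizer.mean.size} covariates, got {covariates.size}")
    if not np.all(np.isfinite(covariates)):
        raise ValueError("covariates must be finite (no missing values)")
    x = standardizer.transform(covariates[None, :])
    mean, var = gpr_predict(model, x)
    return PredictiveEstimate(baseline_fas_pct + float(mean[0]), float(var[0]))


@dataclass
class Standardizer:
    """Column-wise zero-mean/unit-variance scaling on training statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, float))
        sd = X.std(axis=0)
        return cls(X.mean(axis=0), np.where(sd > 1e-12, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.sd
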