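"""Leave-one-subject-out cross-validation, metrics and diagnostics.

Each fold holds out one subject's post-treatment data. On the remaining
subjects the harness (a) selects features and fits one GPR per motor task
on baseline + post-treatment repetitions, (b) fits the clinical
change-score GPR, (c) obtains *out-of-fold* clinical and sensor estimates
for the training subjects through an exact inner leave-one-subject-out
pass (closed-form leave-block-out GP posteriors with fold-level
hyperparameters), (d) fits the fusion weights on those estimates, and then
predicts the held-out subject's post-treatment total FAS with all six
methods: sensor-only, clinical-only, averaging, variance weighting, the
oracle upper bound, and the proposed covariate-conditioned fusion.

Summary metrics per method: RMSE, Pearson r with a Fisher-z 95 % CI, bias
(mean of prediction minus truth) and the SD of the error (population
convention, so RMSE^2 = bias^2 + SD^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from .estimators import (GPRConfig, Standardizer, clinical_post_estimate,
                         estimate_task_scores, gpr_fit, gpr_predict,
                         loo_block_predict, total_fas_percent,
                         FAS_SLOPE, FAS_MAX_POINTS)
from .fusion import (FusionTrainingSet, averaging_weights, fit_fusion,
                     fuse_predict, upper_bound_select, variance_weights)
from .synthgen import COVARIATE_NAMES, SyntheticDataset, TASK_IDS

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "METHODS",
    "plan_folds",
    "run_losocv",
    "compute_metrics",
    "error_vs_change",
    "compare_groups",
    "observed_totals",
]

METHODS = ("sensor", "clinical", "averaging", "variance", "upper_bound", "proposed")


@dataclass(frozen=True)
class FoldPlan:
    """One LOSOCV fold: the held-out subject and the training subjects."""

    held_out: str
    training: tuple[str, ...]


def plan_folds(subject_ids: list[str]) -> list[FoldPlan]:
    ids = list(subject_ids)
    if len(ids) < 3:
        raise ValueError("LOSOCV requires at least 3 subjects")
    return [FoldPlan(h, tuple(s for s in ids if s != h)) for h in ids]


@dataclass
class EvaluationReport:
    """Per-subject out-of-fold predictions and summary metrics."""

    predictions: pd.DataFrame       # subject_id, y_true, change_true, <method> columns
    theta: pd.DataFrame             # per-fold fusion weights (6 covariates)
    omega_c: pd.Series              # per-fold clinical weight of the held-out subject
    seed: int | None = None
    config_hash: str = ""

    def errors(self, method: str) -> np.ndarray:
        return (self.predictions[method] - self.predictions["y_true"]).to_numpy()

    def summary(self) -> pd.DataFrame:
        rows = []
        for method in METHODS:
            m = compute_metrics(self.predictions["y_true"].to_numpy(),
                                self.predictions[method].to_numpy())
            rows.append({"method": method, **m})
        return pd.DataFrame(rows).set_index("method")

    def theta_summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.theta.mean(), "sd": self.theta.std()})

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "config_hash": self.config_hash,
            "summary": self.summary().reset_index().to_dict(orient="records"),
            "theta_mean": self.theta.mean().to_dict(),
            "theta_sd": self.theta.std().to_dict(),
            "omega_c_mean": float(self.omega_c.mean()),
            "predictions": self.predictions.to_dict(orient="records"),
        }, indent=1, default=float)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.predictions.to_csv(out / "per_subject_predictions.csv", index=False)
        self.theta.to_csv(out / "theta_per_fold.csv", index=False)
        summary = self.summary()
        with open(out / "summary.md", "w") as fh:
            fh.write("| Method | RMSE | r (95% CI) | Bias | SD |\n")
            fh.write("|---|---|---|---|---|\n")
            for method, row in summary.iterrows():
                ci = (f"{row['r']:.2f} ({row['r_ci_low']:.2f}, "
                      f"{row['r_ci_high']:.2f})")
                fh.write(f"| {method} | {row['rmse']:.1f}% | {ci} | "
                         f"{row['bias']:.1f}% | {row['sd']:.1f}% |\n")


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """RMSE, Pearson r with Fisher-z 95 % CI, bias and error SD.

    Bias is ``mean(y_hat - y)``; the error SD uses the population
    convention so that RMSE^2 = bias^2 + SD^2 exactly. If either vector
    has zero variance the correlation is reported as NaN.
    """
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("y and y_hat must have equal length >= 2")
    err = y_hat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(err.mean())
    sd = float(err.std(ddof=0))
    if y.std() < 1e-12 or y_hat.std() < 1e-12:
        r = r_lo = r_hi = float("nan")
    else:
        r = float(np.corrcoef(y, y_hat)[0, 1])
        n = y.size
        if n > 3 and abs(r) < 1.0:
            z = np.arctanh(r)
            half = 1.959963984540054 / np.sqrt(n - 3)
            r_lo, r_hi = float(np.tanh(z - half)), float(np.tanh(z + half))
        else:
            r_lo = r_hi = r
    return {"rmse": rmse, "r": r, "r_ci_low": r_lo, "r_ci_high": r_hi,
            "bias": bias, "sd": sd}


def error_vs_change(errors: np.ndarray, true_change: np.ndarray) -> dict[str, float]:
    """Regression of estimation error on the true FAS change.

    A significantly negative slope means the method over-estimates small
    responders and under-estimates large responders (regression to the
    cohort mean); an unbiased method shows a slope whose CI covers 0.
    """
    errors = np.asarray(errors, float).ravel()
    true_change = np.asarray(true_change, float).ravel()
    if errors.size != true_change.size or errors.size < 3:
        raise ValueError("paired vectors of length >= 3 required")
    res = stats.linregress(true_change, errors)
    n = errors.size
    tcrit = stats.t.ppf(0.975, n - 2)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue),
            "slope_ci_low": float(res.slope - tcrit * res.stderr),
            "slope_ci_high": float(res.slope + tcrit * res.stderr)}


def compare_groups(errors_a: np.ndarray, errors_b: np.ndarray) -> dict[str, float]:
    """Welch unpaired t-test between two groups' estimation errors."""
    a = np.asarray(errors_a, float).ravel()
    b = np.asarray(errors_b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = float(a.mean() == b.mean())
        return {"t": 0.0 if equal else float("inf"), "p": 1.0 if equal else 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p)}


def observed_totals(labels: pd.DataFrame) -> pd.DataFrame:
    """Clinician-observed total FAS percent per subject and visit.

    Repetition scores are averaged per task, the eight task means are
    summed and mapped through the task-to-total equation.
    """
    task_means = (labels.groupby(["subject_id", "visit", "task_id"])["fas_score"]
                  .mean().unstack("task_id"))
    fas8 = task_means[list(TASK_IDS)].sum(axis=1)
    pct = fas8.map(total_fas_percent)
    return pct.unstack("visit").rename(columns={"baseline": "fas_baseline_obs",
                                                "post": "fas_post_obs"})


@dataclass
class LosocvConfig:
    """Pipeline settings for one LOSOCV run."""

    # sensor GPRs are refit 8 x n_subjects times per run; the heuristic
    # start is reliable on standardized features, so no extra restarts
    gpr_sensor: GPRConfig = field(default_factory=lambda: GPRConfig(n_restarts=0,
                                                                    maxiter=40))
    gpr_clinical: GPRConfig = field(default_factory=lambda: GPRConfig(n_restarts=2))
    cfs_max_features: int = 20
    cfs_stall_limit: int = 5
    variance_convention: str = "as_printed"
    fusion_ridge: float = 1e-8
    #: include the held-out subject's baseline recordings in sensor training
    include_heldout_baseline: bool = False
    #: fit fusion weights on in-fold (rather than inner out-of-fold) estimates
    fusion_in_fold: bool = False


def run_losocv(dataset: SyntheticDataset,
               feature_tables: dict[str, pd.DataFrame] | None = None,
               config: LosocvConfig | None = None,
               registry: feat.FeatureRegistry | None = None,
               seed: int = 0) -> EvaluationReport:
    """Run the full leave-one-subject-out evaluation on a dataset.

    ``feature_tables`` may be passed pre-computed (they do not depend on
    the fold split); otherwise they are extracted here. Deterministic
    given ``seed``.
    """
    config = config or LosocvConfig()
    if feature_tables is None:
        feature_tables = feat.build_feature_tables(dataset, registry)
    totals = observed_totals(dataset.labels)
    subjects = {s.subject_id: s for s in dataset.subjects}
    ids = [s.subject_id for s in dataset.subjects
           if s.subject_id in totals.index and
           not np.isnan(totals.loc[s.subject_id].get("fas_post_obs", np.nan))]
    skipped = [s.subject_id for s in dataset.subjects if s.subject_id not in ids]
    folds = plan_folds(ids)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(folds) * (len(TASK_IDS) + 2)) % (2**31)
    fold_seeds = fold_seeds.reshape(len(folds), -1)

    # pre-index per-task tables
    task_tables = {}
    feature_cols = {}
    for task, df in feature_tables.items():
        feature_cols[task] = [c for c in df.columns
                              if c not in ("subject_id", "visit", "repetition",
                                           "target_fas")]
        task_tables[task] = df

    rows = []
    theta_rows = []
    omega_rows = []
    for f_idx, fold in enumerate(folds):
        train_ids = list(fold.training)
        held = fold.held_out
        n_tr = len(train_ids)
        pos = {sid: i for i, sid in enumerate(train_ids)}

        # --- per-task sensor GPRs with inner leave-subject-out estimates
        # sensor task-score predictions (mean over reps) for training subjects
        train_task_means = np.zeros((n_tr, len(TASK_IDS)))
        train_task_vars = np.zeros((n_tr, len(TASK_IDS)))
        train_task_means_infold = np.zeros((n_tr, len(TASK_IDS)))
        held_preds: dict[str, np.ndarray] = {}
        held_vars: dict[str, np.ndarray] = {}
        for t_idx, task in enumerate(TASK_IDS):
            df = task_tables[task]
            cols = feature_cols[task]
            in_train = df["subject_id"].isin(train_ids).to_numpy()
            if not config.include_heldout_baseline:
                train_df = df[in_train]
            else:
                train_df = df[in_train | ((df["subject_id"] == held) &
                                          (df["visit"] == "baseline"))]
            X_raw = train_df[cols].to_numpy(float)
            y_rep = train_df["target_fas"].to_numpy(float)
            scaler = Standardizer.fit(X_raw)
            Xs = pd.DataFrame(scaler.transform(X_raw), columns=cols,
                              index=train_df.index)
            sel = feat.cfs_select(Xs, y_rep, max_features=config.cfs_max_features,
                                  stall_limit=config.cfs_stall_limit)
            sel_cols = sel.subset or cols[:1]
            Xsel = Xs[sel_cols].to_numpy(float)
            model = gpr_fit(Xsel, y_rep, config.gpr_sensor,
                            seed=int(fold_seeds[f_idx, t_idx]))

            # inner leave-subject-out: post-visit rows of each training subject
            sid_arr = train_df["subject_id"].to_numpy()
            visit_arr = train_df["visit"].to_numpy()
            blocks, post_masks, block_sids = [], [], []
            for sid in train_ids:
                block = np.flatnonzero(sid_arr == sid)
                if block.size == 0:
                    continue
                blocks.append(block)
                post_masks.append(visit_arr[block] == "post")
                block_sids.append(sid)
            mus, covs = loo_block_predict(model, blocks)
            for sid, block, mask, mu, cov in zip(block_sids, blocks, post_masks,
                                                 mus, covs):
                mrep = np.clip(mu[mask], 0.0, 5.0)
                k = mrep.size
                train_task_means[pos[sid], t_idx] = mrep.mean()
                train_task_vars[pos[sid], t_idx] = cov[np.ix_(mask, mask)].sum() / k**2
            if config.fusion_in_fold:
                mu_in, _ = gpr_predict(model, Xsel)
                mu_in = np.clip(mu_in, 0.0, 5.0)
                for sid, block, mask in zip(block_sids, blocks, post_masks):
                    train_task_means_infold[pos[sid], t_idx] = mu_in[block][mask].mean()

            # held-out subject's post repetitions
            held_df = df[(df["subject_id"] == held) & (df["visit"] == "post")]
            Xh = scaler.transform(held_df[cols].to_numpy(float))
            Xh = pd.DataFrame(Xh, columns=cols)[sel_cols].to_numpy(float)
            mu_h, cov_h = gpr_predict(model, Xh, full_cov=True)
            held_preds[task] = np.clip(mu_h, 0.0, 5.0)
            held_vars[task] = cov_h

        y_s_train = np.array([total_fas_percent(min(train_task_means[i].sum(), 40.0))
                              for i in range(n_tr)])
        scale = (FAS_SLOPE / FAS_MAX_POINTS * 100.0) ** 2
        V_s_train = train_task_vars.sum(axis=1) * scale

        held_scores = estimate_task_scores(held_preds, held_vars)
        y_s_held = held_scores.fas_total_pct
        V_s_held = held_scores.fas_total_pct_variance

        # --- clinical change-score GPR with inner leave-one-out
        cov_train = np.array([subjects[sid].covariates() for sid in train_ids])
        # the FAS-baseline covariate is the clinician-observed baseline total
        base_obs = totals.loc[train_ids, "fas_baseline_obs"].to_numpy()
        post_obs = totals.loc[train_ids, "fas_post_obs"].to_numpy()
        cov_train[:, 5] = base_obs
        delta = post_obs - base_obs
        c_scaler = Standardizer.fit(cov_train)
        Xc_std = c_scaler.transform(cov_train)
        c_model = gpr_fit(Xc_std, delta, config.gpr_clinical,
                          seed=int(fold_seeds[f_idx, len(TASK_IDS)]))
        mus, covs = loo_block_predict(c_model, [np.array([i]) for i in range(n_tr)])
        delta_loo = np.array([m[0] for m in mus])
        V_c_train = np.array([c[0, 0] for c in covs])
        y_c_train = base_obs + delta_loo

        held_cov = subjects[held].covariates()
        held_base_obs = float(totals.loc[held, "fas_baseline_obs"])
        held_cov[5] = held_base_obs
        c_est = clinical_post_estimate(held_cov, held_base_obs, c_model, c_scaler)
        y_c_held, V_c_held = c_est.mean, c_est.variance

        # --- fusion weights, trained by default on the inner out-of-fold
        # estimates (the in-fold option uses full-fold model predictions)
        if config.fusion_in_fold:
            y_s_fit = np.array([
                total_fas_percent(min(train_task_means_infold[i].sum(), 40.0))
                for i in range(n_tr)])
            mu_c_in, _ = gpr_predict(c_model, Xc_std)
            y_c_fit = base_obs + mu_c_in
        else:
            y_s_fit, y_c_fit = y_s_train, y_c_train
        f_training = FusionTrainingSet(Xc_std, y_c_fit, y_s_fit, post_obs)
        f_model = fit_fusion(f_training, ridge=config.fusion_ridge,
                             standardizer=c_scaler)

        # --- held-out predictions, all six methods
        y_true = float(totals.loc[held, "fas_post_obs"])
        fused = fuse_predict(f_model, held_cov, y_c_held, y_s_held)
        avg = averaging_weights(y_c_held, y_s_held)
        var_w = variance_weights(V_c_held, V_s_held, y_c_held, y_s_held,
                                 convention=config.variance_convention)
        ub, _ = upper_bound_select([y_c_held], [y_s_held], [y_true])

        rows.append({
            "subject_id": held,
            "group": subjects[held].group,
            "y_true": y_true,
            "change_true": y_true - held_base_obs,
            "sensor": y_s_held,
            "clinical": y_c_held,
            "averaging": avg.fused,
            "variance": var_w.fused,
            "upper_bound": float(ub[0]),
            "proposed": fused.fused,
            "V_sensor": V_s_held,
            "V_clinical": V_c_held,
        })
        theta_rows.append(dict(zip(COVARIATE_NAMES, f_model.theta)))
        omega_rows.append(fused.omega_c)

    report = EvaluationReport(
        predictions=pd.DataFrame(rows),
        theta=pd.DataFrame(theta_rows),
        omega_c=pd.Series(omega_rows, name="omega_c"),
        seed=seed,
        config_hash=dataset.config_hash,
    )
    if skipped:
        import logging
        logging.getLogger(__name__).info(
            "skipped subjects without post-treatment data: %s", skipped)
    return report
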