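"""Synthetic cohorts and accelerometer recordings for pipeline testing.

The study this package models collected multi-sensor accelerometer data
from stroke and TBI survivors performing eight Wolf Motor Function Test
tasks at a baseline and a post-treatment visit, with clinician-provided
Functional Ability Scale (FAS) ratings per task repetition. No raw cohort
data are publicly deposited, so this module generates cohorts and
recordings carrying the statistical structure the downstream analysis
assumes:

* cohort covariate marginals on the scale of the published cohort summary
  (baseline total FAS ~60 +/- 15 % of full scale, FMA-UE in [15, 55], a
  mean treatment response of ~15 %-points);
* heterogeneous treatment response only partially explained by the six
  clinical covariates (a linear model explains roughly 40-50 % of the
  variance in true FAS change, the rest is an idiosyncratic
  responder/non-responder mixture);
* per-task 0-5 scores consistent with the subject-level total through the
  eight-task-to-total mapping, and rater labels with ~2.5 % repetition
  variability;
* accelerometer signals whose speed, smoothness and trunk compensation
  degrade monotonically with impairment, built from analytic minimum-jerk
  reach profiles plus corrective submovements and band-limited tremor.

The generative constants have no counterpart in the source study; they are
artifact choices exposed through :class:`RecordingConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .estimators import FAS_INTERCEPT, FAS_SLOPE, invert_total_fas_percent

__all__ = [
    "CohortConfig",
    "RecordingConfig",
    "SubjectRecord",
    "Recording",
    "SyntheticDataset",
    "TASK_IDS",
    "MANIPULATION_TASKS",
    "REACHING_TASKS",
    "SENSORS",
    "SENSOR_AXES",
    "generate_cohort",
    "simulate_recording",
    "simulate_rater",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# The eight WMFT tasks used: four Reaching Tasks (single movement
# component) and four Manipulation Tasks (reach / manipulate / return).
REACHING_TASKS = (
    "forearm_to_table",
    "extend_elbow",
    "hand_to_table",
    "reach_retrieve",
)
MANIPULATION_TASKS = ("lift_can", "lift_pencil", "flip_cards", "turn_key")
TASK_IDS = REACHING_TASKS + MANIPULATION_TASKS

SENSORS = ("sternum", "arm", "wrist", "thumb", "index")
#: hardware channel counts: 3-axis units on sternum/arm/wrist, 2-axis on fingers
SENSOR_AXES = {"sternum": 3, "arm": 3, "wrist": 3, "thumb": 2, "index": 2}

# Fixed unit direction of the primary movement per sensor (arbitrary but
# constant body-frame conventions; two-axis finger sensors are simulated by
# projecting the 3-D acceleration onto their first two axes).
_SENSOR_DIR = {
    "wrist": np.array([0.70, 0.55, 0.46]),
    "arm": np.array([0.80, 0.35, 0.49]),
    "thumb": np.array([0.62, 0.66, 0.42]),
    "index": np.array([0.58, 0.70, 0.41]),
    "sternum": np.array([0.20, 0.90, 0.39]),
}
_SENSOR_DIR = {k: v / np.linalg.norm(v) for k, v in _SENSOR_DIR.items()}
#: relative amplitude of the reach acceleration seen at each sensor
_SENSOR_GAIN = {"wrist": 1.0, "arm": 0.6, "thumb": 0.9, "index": 0.9}


@dataclass
class CohortConfig:
    """Distribution parameters for a synthetic cohort.

    Covariate units: age [years], chronicity [days], treatment length
    [days], sessions [count], FMA-UE [points, 0-66], FAS [% of full scale].
    The response model draws the true FAS change as a linear function of
    the standardized covariates plus a two-component responder mixture, so
    clinical information is predictive but incomplete.
    """

    n_subjects: int = 40
    age_mean: float = 45.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (18.0, 80.0)
    chronicity_log_mean: float = 5.5   # ~245 days median
    chronicity_log_sd: float = 1.0
    chronicity_min_days: float = 30.0
    treatment_length_mean: float = 45.0
    treatment_length_sd: float = 15.0
    treatment_length_range: tuple[float, float] = (7.0, 120.0)
    n_sessions_mean: float = 20.0
    n_sessions_sd: float = 8.0
    n_sessions_range: tuple[float, float] = (2.0, 60.0)
    fma_mean: float = 35.0
    fma_sd: float = 10.0
    fma_range: tuple[float, float] = (15.0, 55.0)   # eligibility window
    fas_baseline_mean: float = 60.5
    fas_baseline_sd: float = 15.2
    fas_baseline_range: tuple[float, float] = (10.0, 95.0)
    #: mean true FAS change [%-points] and covariate coefficients per SD
    change_mean: float = 15.0
    coef_n_sessions: float = 5.0
    coef_chronicity: float = -3.0
    coef_fma: float = 2.0
    coef_fas_baseline: float = -3.0
    coef_age: float = -1.0
    coef_treatment_length: float = 1.0
    #: responder mixture: with prob. `responder_prop` the idiosyncratic term
    #: is N(responder_shift, responder_sd^2), else N(nonresponder_shift, ...)
    responder_prop: float = 0.35
    responder_shift: float = 4.0
    responder_sd: float = 8.0
    nonresponder_shift: float = -2.15
    nonresponder_sd: float = 6.0
    #: rater repetition variability as % of the 5-point task scale
    rater_noise_sd_pct: float = 2.5
    #: SD of task-specific jitter around the per-task mean score [0-5 points]
    task_jitter_sd: float = 0.15
    stroke_fraction: float = 0.5

    def validate(self) -> None:
        vals = [v for v in asdict(self).values() if isinstance(v, (int, float))]
        if not np.all(np.isfinite(vals)):
            raise ValueError("CohortConfig parameters must be finite")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for name in ("age_sd", "chronicity_log_sd", "treatment_length_sd",
                     "n_sessions_sd", "fma_sd", "fas_baseline_sd", "responder_sd",
                     "nonresponder_sd", "rater_noise_sd_pct", "task_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.responder_prop <= 1.0:
            raise ValueError("responder_prop must lie in [0, 1]")


@dataclass
class RecordingConfig:
    """Kinematic constants of the synthetic reach model (artifact choices)."""

    sample_rate: float = 51.2
    reach_distance_m: float = 0.35
    base_duration_s: float = 1.0
    #: movement duration scales by (1 + duration_slowing * q), q = impairment
    duration_slowing: float = 1.5
    #: Poisson rate of corrective submovements at full impairment (q = 1)
    submovement_rate: float = 4.0
    submovement_amp: float = 0.25
    submovement_duration_s: float = 0.25
    #: RMS of band-limited tremor at full impairment [m/s^2]
    tremor_rms: float = 0.5
    tremor_band_hz: tuple[float, float] = (4.0, 10.0)
    #: sternum (trunk compensation) amplitude relative to the reach at q = 1
    sternum_gain: float = 0.6
    #: sensor noise floor [m/s^2] on every channel
    noise_floor: float = 0.02
    #: manipulation phase duration relative to the reach duration
    manipulation_factor: float = 1.3
    rest_pad_s: float = 0.3
    touch_margin_s: float = 0.15


@dataclass
class SubjectRecord:
    """Clinical covariates and true/post FAS state for one subject."""

    subject_id: str
    group: Literal["stroke", "tbi"]
    chronicity_days: float
    age_years: float
    treatment_length_days: float
    n_sessions: int
    fma_ue_baseline: float
    fas_baseline_pct: float
    fas_post_pct: float
    #: true (latent) per-task scores, 8 values in [0, 5] per visit
    task_scores_baseline: np.ndarray = field(default_factory=lambda: np.zeros(8))
    task_scores_post: np.ndarray = field(default_factory=lambda: np.zeros(8))

    def __post_init__(self) -> None:
        self.task_scores_baseline = np.asarray(self.task_scores_baseline, float)
        self.task_scores_post = np.asarray(self.task_scores_post, float)
        if self.chronicity_days <= 0:
            raise ValueError("chronicity_days must be positive")
        for arr in (self.task_scores_baseline, self.task_scores_post):
            if arr.size and ((arr < 0).any() or (arr > 5).any()):
                raise ValueError("per-task scores must lie in [0, 5]")
        for pct in (self.fas_baseline_pct, self.fas_post_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("FAS percentages must lie in [0, 100]")

    def task_scores(self, visit: str) -> np.ndarray:
        return self.task_scores_baseline if visit == "baseline" else self.task_scores_post

    def covariates(self) -> np.ndarray:
        """Six clinical covariates in the canonical order."""
        return np.array([
            self.chronicity_days, self.age_years, self.treatment_length_days,
            float(self.n_sessions), self.fma_ue_baseline, self.fas_baseline_pct,
        ])


COVARIATE_NAMES = (
    "chronicity_days", "age_years", "treatment_length_days",
    "n_sessions", "fma_ue_baseline", "fas_baseline_pct",
)


@dataclass
class Recording:
    """Synchronized multi-sensor accelerometer data for one task repetition."""

    subject_id: str
    visit: Literal["baseline", "post"]
    task_id: str
    repetition: int
    sample_rate: float
    channels: dict[str, np.ndarray]   # sensor -> (n_samples, n_axes) in m/s^2
    touch: np.ndarray | None = None   # binary, manipulation tasks only

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lengths = {ch.shape[0] for ch in self.channels.values()}
        if self.touch is not None:
            lengths.add(self.touch.shape[0])
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        is_manip = self.task_id in MANIPULATION_TASKS
        if is_manip and self.touch is None:
            raise ValueError("manipulation-task recordings require a touch channel")
        if not is_manip and self.touch is not None:
            raise ValueError("reaching-task recordings must not carry a touch channel")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def is_manipulation(self) -> bool:
        return self.task_id in MANIPULATION_TASKS

    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.visit, self.task_id, self.repetition)


@dataclass
class SyntheticDataset:
    """A cohort with its recordings and per-repetition rater labels."""

    subjects: list[SubjectRecord]
    recordings: dict[tuple[str, str, str, int], Recording]
    labels: pd.DataFrame    # subject_id, visit, task_id, repetition, fas_score
    config_hash: str = ""
    seed: int | None = None


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a synthetic cohort; deterministic given ``(config, seed)``.

    The true post-treatment total FAS is ``baseline + Delta`` where
    ``Delta`` is linear in the standardized covariates plus the responder
    mixture, clipped to the scale. Per-task true scores are derived by
    inverting the eight-task-to-total mapping and adding small
    task-specific jitter, so task-level and total-level scores stay
    approximately consistent.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    if n == 0:
        return []

    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range, n)
    chron = np.maximum(
        rng.lognormal(config.chronicity_log_mean, config.chronicity_log_sd, n),
        config.chronicity_min_days,
    )
    tlen = _truncated_normal(rng, config.treatment_length_mean,
                             config.treatment_length_sd,
                             *config.treatment_length_range, n)
    nsess = np.round(_truncated_normal(rng, config.n_sessions_mean, config.n_sessions_sd,
                                       *config.n_sessions_range, n)).astype(int)
    fma = _truncated_normal(rng, config.fma_mean, config.fma_sd, *config.fma_range, n)
    fas0 = _truncated_normal(rng, config.fas_baseline_mean, config.fas_baseline_sd,
                             *config.fas_baseline_range, n)

    # standardize with the *configured* moments so subjects are i.i.d.
    def z(x, mean, sd):
        return (x - mean) / sd if sd > 0 else np.zeros_like(x)

    signal = (
        config.coef_n_sessions * z(nsess, config.n_sessions_mean, config.n_sessions_sd)
        + config.coef_chronicity * z(np.log(chron), config.chronicity_log_mean,
                                     config.chronicity_log_sd)
        + config.coef_fma * z(fma, config.fma_mean, config.fma_sd)
        + config.coef_fas_baseline * z(fas0, config.fas_baseline_mean, config.fas_baseline_sd)
        + config.coef_age * z(age, config.age_mean, config.age_sd)
        + config.coef_treatment_length * z(tlen, config.treatment_length_mean,
                                           config.treatment_length_sd)
    )
    responder = rng.random(n) < config.responder_prop
    idio = np.where(
        responder,
        rng.normal(config.responder_shift, config.responder_sd, n),
        rng.normal(config.nonresponder_shift, config.nonresponder_sd, n),
    )
    delta = config.change_mean + signal + idio
    fas1 = np.clip(fas0 + delta, 0.0, 100.0)

    n_stroke = int(round(config.stroke_fraction * n))
    groups = np.array(["stroke"] * n_stroke + ["tbi"] * (n - n_stroke))

    subjects = []
    for i in range(n):
        tb = _per_task_scores(fas0[i], rng, config.task_jitter_sd)
        tp = _per_task_scores(fas1[i], rng, config.task_jitter_sd)
        subjects.append(SubjectRecord(
            subject_id=f"S{i:03d}",
            group=groups[i],
            chronicity_days=float(chron[i]),
            age_years=float(age[i]),
            treatment_length_days=float(tlen[i]),
            n_sessions=int(nsess[i]),
            fma_ue_baseline=float(fma[i]),
            fas_baseline_pct=float(fas0[i]),
            fas_post_pct=float(fas1[i]),
            task_scores_baseline=tb,
            task_scores_post=tp,
        ))
    return subjects


def _per_task_scores(total_pct: float, rng: np.random.Generator,
                     jitter_sd: float) -> np.ndarray:
    """Invert the total-percent mapping to eight per-task 0-5 scores."""
    fas8 = invert_total_fas_percent(total_pct)
    base = fas8 / 8.0
    return np.clip(base + rng.normal(0.0, jitter_sd, 8), 0.0, 5.0)


def simulate_rater(true_score: float, noise_sd_pct: float,
                   rng: np.random.Generator | int | None = None,
                   round_to_int: bool = False) -> float:
    """Observed per-repetition rater score for a true 0-5 task score.

    Gaussian noise with SD ``noise_sd_pct`` percent of the 5-point scale
    emulates repetition-to-repetition rating variability; the result is
    clipped to [0, 5] and, optionally, rounded to the integer scale.
    """
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    if not 0.0 <= true_score <= 5.0:
        raise ValueError(f"true_score must lie in [0, 5], got {true_score}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    observed = true_score + rng.normal(0.0, noise_sd_pct / 100.0 * 5.0)
    observed = float(np.clip(observed, 0.0, 5.0))
    return float(round(observed)) if round_to_int else observed


def _minimum_jerk_accel(n: int, duration_s: float, distance_m: float,
                        sample_rate: float) -> np.ndarray:
    """Analytic acceleration of a minimum-jerk reach sampled at ``n`` points.

    Position x(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5) gives
    a(t) = D / T^2 (60 tau - 180 tau^2 + 120 tau^3) for tau in [0, 1].
    """
    t = np.arange(n) / sample_rate
    tau = np.clip(t / duration_s, 0.0, 1.0)
    return distance_m / duration_s**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)


def _bandlimited_tremor(rng: np.random.Generator, n: int, rms: float,
                        band: tuple[float, float], sample_rate: float) -> np.ndarray:
    if rms <= 0 or n < 24:
        return np.zeros(n)
    from scipy import signal as sps
    sos = sps.butter(2, band, btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    cur = float(np.sqrt(np.mean(x**2)))
    return x * (rms / cur) if cur > 0 else x


def _phase_hand_accel(rng: np.random.Generator, q: float, duration_s: float,
                      cfg: RecordingConfig, active: bool = True) -> np.ndarray:
    """Scalar acceleration profile of the hand for one movement phase."""
    n = max(int(round(duration_s * cfg.sample_rate)), 8)
    a = np.zeros(n)
    if active:
        a += _minimum_jerk_accel(n, duration_s, cfg.reach_distance_m, cfg.sample_rate)
        # corrective submovements: scaled minimum-jerk pulses at random onsets
        n_sub = rng.poisson(cfg.submovement_rate * q)
        peak = 5.7735 * cfg.reach_distance_m / duration_s**2
        for _ in range(n_sub):
            onset = int(rng.uniform(0.1, 0.75) * n)
            dur = cfg.submovement_duration_s * rng.uniform(0.8, 1.2)
            m = max(int(round(dur * cfg.sample_rate)), 4)
            pulse = _minimum_jerk_accel(m, dur, 1.0, cfg.sample_rate)
            pulse *= cfg.submovement_amp * q * peak / (np.abs(pulse).max() + 1e-12)
            end = min(onset + m, n)
            a[onset:end] += pulse[: end - onset] * rng.choice([-1.0, 1.0])
    a += _bandlimited_tremor(rng, n, cfg.tremor_rms * q, cfg.tremor_band_hz,
                             cfg.sample_rate)
    return a


def simulate_recording(subject: SubjectRecord, task_id: str, repetition: int,
                       visit: str, seed: int | None = None,
                       config: RecordingConfig | None = None) -> Recording:
    """Simulate one task repetition for a subject at a visit.

    The wrist/arm/finger channels carry a minimum-jerk reach whose duration
    scales with impairment ``q = (5 - s)/5``, plus Poisson corrective
    submovements and band-limited tremor with amplitude proportional to
    ``q``. The sternum channel carries slow trunk-compensation motion with
    amplitude proportional to ``q``. Manipulation tasks contain three
    movement phases and a touch channel with one contact interval.
    """
    cfg = config or RecordingConfig()
    task_index = TASK_IDS.index(task_id)
    s = float(subject.task_scores(visit)[task_index])
    if not 0.0 <= s <= 5.0:
        raise ValueError(f"true task score must lie in [0, 5], got {s}")
    q = (5.0 - s) / 5.0
    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate
    is_manip = task_id in MANIPULATION_TASKS

    T = cfg.base_duration_s * (1.0 + cfg.duration_slowing * q) \
        * (0.9 + 0.2 * (task_index % 4) / 3.0)
    pad = max(int(round(cfg.rest_pad_s * fs)), 8)

    # scalar hand-acceleration profile per phase
    phases = [np.zeros(pad), _phase_hand_accel(rng, q, T, cfg)]
    if is_manip:
        phase_bounds_start = sum(len(p) for p in phases)
        manip = _phase_hand_accel(rng, q, cfg.manipulation_factor * T, cfg)
        phases.append(manip)
        phase_bounds_end = phase_bounds_start + len(manip)
        phases.append(_phase_hand_accel(rng, q, T, cfg))
    phases.append(np.zeros(pad))
    hand = np.concatenate(phases)
    n = hand.size

    channels: dict[str, np.ndarray] = {}
    for sensor in ("wrist", "arm", "thumb", "index"):
        gain = _SENSOR_GAIN[sensor]
        vec = hand[:, None] * (_SENSOR_DIR[sensor] * gain)[None, :]
        vec = vec + rng.normal(0.0, cfg.noise_floor, vec.shape)
        if sensor in ("thumb", "index"):
            vec = vec[:, :2]   # two-axis finger units
        channels[sensor] = vec

    # trunk compensation: one slow minimum-jerk lean spanning the recording
    lean = _minimum_jerk_accel(n, n / fs, cfg.reach_distance_m, fs)
    sternum = q * cfg.sternum_gain * lean
    sternum = sternum + _bandlimited_tremor(rng, n, 0.3 * cfg.tremor_rms * q,
                                            cfg.tremor_band_hz, fs)
    stern3 = sternum[:, None] * _SENSOR_DIR["sternum"][None, :]
    channels["sternum"] = stern3 + rng.normal(0.0, cfg.noise_floor, stern3.shape)

    touch = None
    if is_manip:
        touch = np.zeros(n)
        margin = int(round(cfg.touch_margin_s * fs))
        on = phase_bounds_start + margin
        off = phase_bounds_end - margin
        touch[on:off] = 1.0

    return Recording(subject.subject_id, visit, task_id, repetition, fs,
                     channels, touch)


def generate_dataset(config: CohortConfig | None = None,
                     recording_config: RecordingConfig | None = None,
                     seed: int = 0, n_repetitions: int = 3,
                     visits: Iterable[str] = ("baseline", "post")) -> SyntheticDataset:
    """Generate a full dataset: cohort, recordings and rater labels."""
    config = config or CohortConfig()
    rcfg = recording_config or RecordingConfig()
    ss = np.random.SeedSequence(seed)
    cohort_seed, rec_seed_root, rater_seed = ss.spawn(3)
    cohort = generate_cohort(config, seed=cohort_seed)
    rater_rng = np.random.default_rng(rater_seed)

    recordings: dict[tuple[str, str, str, int], Recording] = {}
    rows = []
    rec_children = iter(rec_seed_root.spawn(
        max(len(cohort), 1) * len(TASK_IDS) * n_repetitions * 2))
    for subject in cohort:
        for visit in visits:
            scores = subject.task_scores(visit)
            for ti, task_id in enumerate(TASK_IDS):
                for rep in range(1, n_repetitions + 1):
                    rec = simulate_recording(subject, task_id, rep, visit,
                                             seed=next(rec_children), config=rcfg)
                    recordings[rec.key()] = rec
                    observed = simulate_rater(float(scores[ti]),
                                              config.rater_noise_sd_pct, rater_rng)
                    rows.append({
                        "subject_id": subject.subject_id, "visit": visit,
                        "task_id": task_id, "repetition": rep,
                        "fas_score": observed,
                    })
    labels = pd.DataFrame(rows, columns=["subject_id", "visit", "task_id",
                                         "repetition", "fas_score"])
    return SyntheticDataset(cohort, recordings, labels,
                            config_hash=config_digest(config, rcfg, seed), seed=seed)


def config_digest(config: CohortConfig, recording_config: RecordingConfig,
                  seed: int | None) -> str:
    payload = {"cohort": asdict(config), "recording": asdict(recording_config),
               "seed": seed}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# plain-text round-trip


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write a dataset as CSVs plus a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)

    cohort_rows = []
    for s in dataset.subjects:
        row = {
            "subject_id": s.subject_id, "group": s.group,
            "chronicity_days": s.chronicity_days, "age_years": s.age_years,
            "treatment_length_days": s.treatment_length_days,
            "n_sessions": s.n_sessions, "fma_ue_baseline": s.fma_ue_baseline,
            "fas_baseline_pct": s.fas_baseline_pct, "fas_post_pct": s.fas_post_pct,
        }
        for i, task in enumerate(TASK_IDS):
            row[f"true_{task}_baseline"] = s.task_scores_baseline[i]
            row[f"true_{task}_post"] = s.task_scores_post[i]
        cohort_rows.append(row)
    pd.DataFrame(cohort_rows).to_csv(out / "cohort.csv", index=False)
    dataset.labels.to_csv(out / "labels.csv", index=False)

    files = []
    for key, rec in dataset.recordings.items():
        sid, visit, task, rep = key
        name = f"{sid}_{visit}_{task}_rep{rep}.csv"
        cols = {"t_s": np.arange(rec.n_samples) / rec.sample_rate}
        for sensor in SENSORS:
            arr = rec.channels[sensor]
            for ax in range(arr.shape[1]):
                cols[f"{sensor}_{'xyz'[ax]}"] = arr[:, ax]
        if rec.touch is not None:
            cols["touch"] = rec.touch.astype(int)
        pd.DataFrame(cols).to_csv(out / "recordings" / name, index=False)
        files.append({"file": f"recordings/{name}", "subject_id": sid,
                      "visit": visit, "task_id": task, "repetition": rep,
                      "sample_rate": rec.sample_rate})

    manifest = {"config_hash": dataset.config_hash, "seed": dataset.seed,
                "n_subjects": len(dataset.subjects),
                "n_recordings": len(files), "recordings": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cohort_df = pd.read_csv(src / "cohort.csv")
    subjects = []
    for _, row in cohort_df.iterrows():
        subjects.append(SubjectRecord(
            subject_id=row["subject_id"], group=row["group"],
            chronicity_days=row["chronicity_days"], age_years=row["age_years"],
            treatment_length_days=row["treatment_length_days"],
            n_sessions=int(row["n_sessions"]),
            fma_ue_baseline=row["fma_ue_baseline"],
            fas_baseline_pct=row["fas_baseline_pct"],
            fas_post_pct=row["fas_post_pct"],
            task_scores_baseline=[row[f"true_{t}_baseline"] for t in TASK_IDS],
            task_scores_post=[row[f"true_{t}_post"] for t in TASK_IDS],
        ))
    labels = pd.read_csv(src / "labels.csv")

    recordings = {}
    for entry in manifest["recordings"]:
        path = src / entry["file"]
        if not path.exists():
            raise FileNotFoundError(
                f"recording listed in manifest is missing: {entry['file']}")
        df = pd.read_csv(path)
        channels = {}
        for sensor in SENSORS:
            axes = [c for c in df.columns if c.startswith(sensor + "_")]
            channels[sensor] = df[axes].to_numpy()
        touch = df["touch"].to_numpy(dtype=float) if "touch" in df.columns else None
        rec = Recording(entry["subject_id"], entry["visit"], entry["task_id"],
                        int(entry["repetition"]), float(entry["sample_rate"]),
                        channels, touch)
        recordings[rec.key()] = rec
    return SyntheticDataset(subjects, recordings, labels,
                            config_hash=manifest["config_hash"],
                            seed=manifest["seed"])
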