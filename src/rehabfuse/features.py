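"""Kinematic feature extraction and correlation-based feature selection.

Features follow the families used for accelerometer-based movement-quality
scoring: per-series summary statistics (min, max, mean, RMS,
dominant-frequency ratio, skewness, excess kurtosis, histogram entropy) on
the magnitude series of displacement, velocity, acceleration and jerk for
each sensor; pairwise Spearman correlations between the acceleration
magnitudes of all sensor pairs (relative movement / trunk compensation);
and movement-component durations. Reaching tasks yield one feature block
over the whole recording; manipulation tasks yield one block per movement
component (reach / manipulate / return) plus per-component durations.

Feature selection uses CFS (correlation-based feature selection): subsets
are scored by the merit

    M(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``r_cf`` is the mean absolute feature-target correlation and
``r_ff`` the mean absolute feature-feature correlation over the k-feature
subset, searched with best-first search (exhaustive search available for
small candidate pools).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import signal as sig
from .synthgen import Recording, SyntheticDataset, SENSORS, MANIPULATION_TASKS

__all__ = [
    "FeatureRegistry",
    "series_features",
    "cross_correlation_features",
    "extract_recording",
    "build_feature_tables",
    "cfs_select",
    "cfs_merit",
    "CfsResult",
    "STAT_NAMES",
]

STAT_NAMES = ("min", "max", "mean", "rms", "domfreq_ratio", "skewness",
              "kurtosis", "entropy")
SERIES_KINDS = ("displacement", "velocity", "acceleration", "jerk")


@dataclass
class FeatureRegistry:
    """Data-driven description of the extracted feature set.

    The registry controls which sensors, series kinds and statistics are
    emitted, so the total feature count is configurable rather than
    hard-coded; :meth:`feature_count` reports the count implied by the
    current settings.
    """

    sensors: tuple[str, ...] = SENSORS
    kinds: tuple[str, ...] = SERIES_KINDS
    stats: tuple[str, ...] = STAT_NAMES
    include_spearman: bool = True
    include_duration: bool = True
    entropy_bins: int = 16
    lowpass_cutoff_hz: float = 8.0
    lowpass_order: int = 6
    highpass_cutoff_hz: float = 0.25
    highpass_order: int = 6
    zero_phase: bool = True
    debounce_ms: float = 100.0

    def block_count(self) -> int:
        n = len(self.sensors) * len(self.kinds) * len(self.stats)
        if self.include_spearman:
            n += len(self.sensors) * (len(self.sensors) - 1) // 2
        return n

    def feature_count(self, task_kind: str) -> int:
        """Total features for a ``reaching`` or ``manipulation`` task."""
        if task_kind == "reaching":
            return self.block_count() + (1 if self.include_duration else 0)
        if task_kind == "manipulation":
            return 3 * self.block_count() + (3 if self.include_duration else 0)
        raise ValueError(f"unknown task kind {task_kind!r}")


def _stats_block(x: np.ndarray, entropy_bins: int) -> dict[str, float]:
    """All summary statistics of one series in a single pass.

    Conventions for degenerate (zero-variance) series: skewness, excess
    kurtosis and entropy are 0 and the dominant-frequency ratio is 0.
    """
    n = x.size
    mean = float(x.mean())
    out = {
        "min": float(x.min()), "max": float(x.max()), "mean": mean,
        "rms": float(np.sqrt(np.mean(x**2))),
    }
    xc = x - mean
    m2 = float(np.mean(xc**2))
    if m2 < 1e-24:
        out.update(domfreq_ratio=0.0, skewness=0.0, kurtosis=0.0, entropy=0.0)
        return out
    out["skewness"] = float(np.mean(xc**3) / m2**1.5)
    out["kurtosis"] = float(np.mean(xc**4) / m2**2 - 3.0)
    # dominant-frequency ratio: periodogram peak power / total power,
    # computed on the mean-removed series so the DC bin is excluded
    p = np.abs(np.fft.rfft(xc))**2
    p = p[1:]
    total = p.sum()
    out["domfreq_ratio"] = float(p.max() / total) if total > 0 else 0.0
    # Shannon entropy (bits) of the fixed-bin amplitude histogram
    counts, _ = np.histogram(x, bins=entropy_bins)
    pk = counts[counts > 0] / n
    out["entropy"] = float(-(pk * np.log2(pk)).sum())
    return out


def series_features(ts: sig.TimeSeries, entropy_bins: int = 16,
                    prefix: str = "") -> dict[str, float]:
    """Summary-statistic features of one time series."""
    if len(ts) < 8:
        raise ValueError("series must contain at least 8 samples")
    block = _stats_block(ts.values, entropy_bins)
    return {f"{prefix}{k}": v for k, v in block.items()}


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected Spearman correlation (average ranks + Pearson)."""
    ra, rb = rankdata(a), rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0   # constant series convention
    return float(np.mean((ra - ra.mean()) * (rb - rb.mean())) / (sa * sb))


def cross_correlation_features(magnitudes: Mapping[str, np.ndarray],
                               prefix: str = "") -> dict[str, float]:
    """Pairwise Spearman correlations of sensor acceleration magnitudes."""
    sensors = list(magnitudes)
    n = {len(v) for v in magnitudes.values()}
    if len(n) > 1:
        raise ValueError("magnitude series must have equal length")
    if n.pop() < 3:
        raise ValueError("series must contain at least 3 samples")
    # rank each series once, then correlate standardized ranks pairwise
    ranks = {}
    for s in sensors:
        r = rankdata(magnitudes[s])
        sd = r.std()
        ranks[s] = (r - r.mean()) / sd if sd > 1e-12 else None
    out = {}
    for s1, s2 in itertools.combinations(sensors, 2):
        r1, r2 = ranks[s1], ranks[s2]
        out[f"{prefix}spearman_{s1}_{s2}"] = (
            0.0 if r1 is None or r2 is None else float(np.mean(r1 * r2)))
    return out


def _process_recording(rec: Recording, registry: FeatureRegistry
                       ) -> dict[str, dict[str, np.ndarray]]:
    """Full-recording magnitude series per sensor and series kind.

    Per axis: low-pass the acceleration, integrate (with drift high-pass)
    to velocity and again to displacement, differentiate to jerk; then form
    the per-sample magnitude across the sensor's axes for each kind. Axes
    are processed as one batch; the result is identical to applying the
    :mod:`rehabfuse.signal` operations axis by axis.
    """
    from scipy import signal as sps
    from scipy.integrate import cumulative_trapezoid

    fs = rec.sample_rate
    sos_lp = sig._design_sos("lowpass", registry.lowpass_order,
                             registry.lowpass_cutoff_hz, fs)
    sos_hp = sig._design_sos("highpass", registry.highpass_order,
                             registry.highpass_cutoff_hz, fs)

    def apply(sos, arr):
        if registry.zero_phase:
            padlen = 3 * (2 * sos.shape[0] + 1)
            if arr.shape[0] <= padlen:
                raise ValueError(
                    f"recording of length {arr.shape[0]} is shorter than the "
                    f"zero-phase filter warm-up ({padlen + 1} samples)")
            return sps.sosfiltfilt(sos, arr, axis=0, padtype="even")
        return sps.sosfilt(sos, arr, axis=0)

    out: dict[str, dict[str, np.ndarray]] = {}
    dx = 1.0 / fs
    for sensor in registry.sensors:
        acc = apply(sos_lp, rec.channels[sensor])
        vel = apply(sos_hp, cumulative_trapezoid(acc, dx=dx, initial=0.0, axis=0))
        disp = apply(sos_hp, cumulative_trapezoid(vel, dx=dx, initial=0.0, axis=0))
        jerk = np.gradient(acc, axis=0) * fs
        out[sensor] = {
            kind: np.sqrt((arr**2).sum(axis=1))
            for kind, arr in (("acceleration", acc), ("velocity", vel),
                              ("displacement", disp), ("jerk", jerk))
        }
    return out


def _block_features(mags: dict[str, dict[str, np.ndarray]],
                    registry: FeatureRegistry, lo: int, hi: int,
                    prefix: str) -> dict[str, float]:
    feats: dict[str, float] = {}
    for sensor in registry.sensors:
        for kind in registry.kinds:
            block = _stats_block(mags[sensor][kind][lo:hi], registry.entropy_bins)
            for stat in registry.stats:
                feats[f"{prefix}{sensor}_{kind}_{stat}"] = block[stat]
    if registry.include_spearman:
        acc = {s: mags[s]["acceleration"][lo:hi] for s in registry.sensors}
        feats.update(cross_correlation_features(acc, prefix=prefix))
    return feats


def extract_recording(rec: Recording,
                      registry: FeatureRegistry | None = None) -> dict[str, float]:
    """Feature vector of one recording.

    Reaching tasks produce one whole-task block; manipulation tasks are
    segmented by the touch channel into reach / manipulate / return and
    produce one block per component plus per-component durations.
    """
    registry = registry or FeatureRegistry()
    mags = _process_recording(rec, registry)
    n = rec.n_samples
    fs = rec.sample_rate
    feats: dict[str, float] = {}
    if rec.is_manipulation:
        if rec.touch is None:
            raise ValueError(f"manipulation task {rec.task_id} lacks a touch channel")
        segs = sig.segment_by_touch(rec.touch, fs, registry.debounce_ms,
                                    recording_id="/".join(map(str, rec.key())))
        for name, (lo, hi) in segs.as_dict().items():
            feats.update(_block_features(mags, registry, lo, hi, f"{name}_"))
            if registry.include_duration:
                feats[f"{name}_duration_s"] = (hi - lo) / fs
    else:
        feats.update(_block_features(mags, registry, 0, n, "task_"))
        if registry.include_duration:
            feats["task_duration_s"] = n / fs
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features extracted: {bad[:5]}")
    return feats


def build_feature_tables(dataset: SyntheticDataset,
                         registry: FeatureRegistry | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Per-task feature tables over all recordings in a dataset.

    Each table has one row per (subject, visit, repetition) with the
    feature columns plus a ``target_fas`` column holding the clinician
    (rater) score for that repetition. Tasks are tabulated separately
    because reaching and manipulation tasks have different feature sets.
    """
    registry = registry or FeatureRegistry()
    labels = dataset.labels.set_index(
        ["subject_id", "visit", "task_id", "repetition"])["fas_score"]
    rows_per_task: dict[str, list[dict]] = {}
    for key in sorted(dataset.recordings):
        rec = dataset.recordings[key]
        feats = extract_recording(rec, registry)
        row = {"subject_id": rec.subject_id, "visit": rec.visit,
               "repetition": rec.repetition, **feats,
               "target_fas": float(labels.loc[key])}
        rows_per_task.setdefault(rec.task_id, []).append(row)
    tables = {}
    for task, rows in rows_per_task.items():
        df = pd.DataFrame(rows)
        if df.isna().any().any():
            raise ValueError(f"feature table for task {task} contains missing values")
        tables[task] = df
    return tables


# ---------------------------------------------------------------------------
# correlation-based feature selection


@dataclass
class CfsResult:
    subset: list[str]
    merit: float
    n_expansions: int = 0


def cfs_merit(r_cf: np.ndarray, r_ff: np.ndarray,
              subset: Iterable[int]) -> float:
    """CFS merit of a feature subset from precomputed |correlations|."""
    idx = list(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    mean_cf = r_cf[idx].mean()
    if k == 1:
        return float(mean_cf)
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = (sub.sum() - np.trace(sub)) / (k * (k - 1))
    return float(k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff))


def _correlations(X: np.ndarray, y: np.ndarray):
    """(|feature-target|, |feature-feature|) Pearson correlation magnitudes."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    ok = sd > 1e-12
    Z = np.where(ok, Xc / np.where(ok, sd, 1.0), 0.0)
    yc = y - y.mean()
    sy = yc.std()
    if sy < 1e-12:
        raise ValueError("target has zero variance; CFS is undefined")
    n = X.shape[0]
    r_cf = np.abs(Z.T @ (yc / sy)) / n
    r_ff = np.abs(Z.T @ Z) / n
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def cfs_select(X, y, search: str = "best_first", max_features: int | None = None,
               stall_limit: int = 5, child_beam: int = 50) -> CfsResult:
    """Select a feature subset maximizing the CFS merit.

    ``X`` may be a DataFrame (feature names preserved) or an array. The
    default best-first search expands the best open subset by one feature
    at a time and stops after ``stall_limit`` consecutive expansions
    without improving the best merit found; on large candidate pools only
    the ``child_beam`` highest-merit children of each expansion are kept
    open (all children are kept when the pool fits in the beam).
    ``search="exhaustive"`` enumerates all non-empty subsets (allowed for
    <= 15 features).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, float))
        names = [f"f{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, float).ravel()
    if Xa.shape[0] < 2:
        raise ValueError("CFS requires at least 2 rows")
    r_cf, r_ff = _correlations(Xa, y)
    p = Xa.shape[1]
    cap = max_features if max_features is not None else min(p, 60)

    if search == "exhaustive":
        if p > 15:
            raise ValueError("exhaustive search is limited to <= 15 features")
        best_idx, best_merit = [], -np.inf
        for k in range(1, min(p, cap) + 1):
            for combo in itertools.combinations(range(p), k):
                m = cfs_merit(r_cf, r_ff, combo)
                if m > best_merit:
                    best_idx, best_merit = list(combo), m
        return CfsResult([names[i] for i in best_idx], best_merit)

    if search != "best_first":
        raise ValueError(f"unknown search strategy {search!r}")

    # Best-first search over subsets, expanding one feature at a time.
    # Child merits for all candidate additions are computed in one
    # vectorized step from the parent's running correlation sums.
    start: frozenset[int] = frozenset()
    counter = itertools.count()   # heap tie-breaker
    # heap entries: (-merit, tiebreak, subset, sum_cf, sum_ff)
    open_heap: list = [(0.0, next(counter), start, 0.0, 0.0)]
    seen = {start}
    best_set, best_merit = start, 0.0
    stall = 0
    expansions = 0
    while open_heap and stall < stall_limit:
        _neg_m, _, node, sum_cf, sum_ff = heapq.heappop(open_heap)
        expansions += 1
        improved = False
        if len(node) < cap:
            idx = np.fromiter(node, int, len(node))
            k = idx.size + 1
            cand = np.ones(p, bool)
            cand[idx] = False
            cand_idx = np.flatnonzero(cand)
            add_ff = r_ff[idx][:, cand_idx].sum(axis=0) if idx.size else \
                np.zeros(cand_idx.size)
            child_cf = sum_cf + r_cf[cand_idx]
            child_ff = sum_ff + add_ff
            mean_ff = 2.0 * child_ff / (k * (k - 1)) if k > 1 else np.zeros_like(child_cf)
            merits = child_cf / np.sqrt(k + k * (k - 1) * mean_ff)
            if cand_idx.size > child_beam:
                keep = np.argpartition(merits, -child_beam)[-child_beam:]
                cand_idx, merits = cand_idx[keep], merits[keep]
                child_cf, child_ff = child_cf[keep], child_ff[keep]
            for pos, j in enumerate(cand_idx):
                child = node | {int(j)}
                if child in seen:
                    continue
                seen.add(child)
                m = float(merits[pos])
                heapq.heappush(open_heap, (-m, next(counter), child,
                                           float(child_cf[pos]), float(child_ff[pos])))
                if m > best_merit + 1e-12:
                    best_set, best_merit = child, m
                    improved = True
        stall = 0 if improved else stall + 1
    ordered = sorted(best_set, key=lambda i: -r_cf[i])
    return CfsResult([names[i] for i in ordered], best_merit, expansions)
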