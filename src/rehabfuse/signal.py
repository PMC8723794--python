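"""Signal-processing chain for wearable accelerometer recordings.

Implements the processing steps applied to each accelerometer axis before
feature extraction: Butterworth filtering (zero-phase by default),
trapezoid-rule integration with drift removal, finite-difference
differentiation, per-sample magnitude series, and touch-based segmentation
of manipulation-task recordings into reach / manipulate / return components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "SegmentSet",
    "SegmentationError",
    "butterworth_filter",
    "integrate_drift_corrected",
    "differentiate",
    "magnitude",
    "segment_by_touch",
]

Kind = Literal["displacement", "velocity", "acceleration", "jerk"]

#: kind produced by one integration step
_INTEGRATES_TO = {"acceleration": "velocity", "velocity": "displacement"}


@dataclass
class TimeSeries:
    """A single-channel (or magnitude) time series at a fixed sample rate.

    Parameters
    ----------
    values
        Sample values; finite floats.
    sample_rate
        Sampling frequency in Hz; must be positive.
    kind
        One of ``displacement``, ``velocity``, ``acceleration``, ``jerk``.
        Units follow the kind (m, m/s, m/s^2, m/s^3).
    """

    values: np.ndarray
    sample_rate: float
    kind: Kind = "acceleration"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate


@dataclass(frozen=True)
class SegmentSet:
    """Half-open sample-index intervals for the three movement components.

    ``reach`` covers lap-to-table transport, ``manipulate`` the object
    interaction, ``return_`` table-to-lap transport. Intervals are ordered,
    non-overlapping and non-empty, and partition ``[reach[0], return_[1])``.
    """

    reach: tuple[int, int]
    manipulate: tuple[int, int]
    return_: tuple[int, int]

    def __post_init__(self) -> None:
        r, m, b = self.reach, self.manipulate, self.return_
        if not (r[0] < r[1] <= m[0] < m[1] <= b[0] < b[1]):
            raise ValueError(f"segments must be ordered and non-empty: {r}, {m}, {b}")
        if r[1] != m[0] or m[1] != b[0]:
            raise ValueError("segments must partition the recording without gaps")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"reach": self.reach, "manipulate": self.manipulate, "return": self.return_}


class SegmentationError(RuntimeError):
    """Raised when a touch channel contains no usable contact interval."""


from functools import lru_cache


@lru_cache(maxsize=64)
def _design_sos(mode: str, order: int, cutoff_hz: float, sample_rate: float) -> np.ndarray:
    nyquist = sample_rate / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist)=(0, {nyquist:g}) Hz, got {cutoff_hz!r}"
        )
    btype = {"lowpass": "lowpass", "highpass": "highpass"}[mode]
    return sps.butter(order, cutoff_hz, btype=btype, fs=sample_rate, output="sos")


@lru_cache(maxsize=64)
def _sos_zi(mode: str, order: int, cutoff_hz: float, sample_rate: float) -> np.ndarray:
    return sps.sosfilt_zi(_design_sos(mode, order, cutoff_hz, sample_rate))


def butterworth_filter(
    ts: TimeSeries,
    mode: Literal["lowpass", "highpass"],
    order: int = 6,
    cutoff_hz: float = 8.0,
    zero_phase: bool = True,
) -> TimeSeries:
    """Apply a Butterworth filter to a time series.

    By default the filter is applied forward-backward (``sosfiltfilt``) so
    the output is zero-phase; the effective magnitude response is then the
    squared magnitude of the designed filter. Set ``zero_phase=False`` for a
    causal single pass. The filter is realized in second-order sections for
    numerical stability at very low normalized cutoffs (0.25 Hz at 51.2 Hz).
    """
    sos = _design_sos(mode, order, cutoff_hz, ts.sample_rate)
    if zero_phase:
        # default padlen used by sosfiltfilt; shorter inputs cannot be padded
        n_sections = sos.shape[0]
        padlen = 3 * (2 * n_sections + 1)
        if len(ts) <= padlen:
            raise ValueError(
                f"series of length {len(ts)} is shorter than the filter warm-up "
                f"({padlen + 1} samples required for zero-phase order-{order} filtering)"
            )
        out = sps.sosfiltfilt(sos, ts.values, padtype="even")
    else:
        if len(ts) < 2:
            raise ValueError("series too short to filter")
        out = sps.sosfilt(sos, ts.values)
    return replace(ts, values=out)


def integrate_drift_corrected(
    ts: TimeSeries,
    highpass_cutoff_hz: float = 0.25,
    highpass_order: int = 6,
    zero_phase: bool = True,
) -> TimeSeries:
    """Integrate a series with the trapezoid rule, then remove drift.

    Cumulative trapezoid integration is followed by a high-pass filter
    (default 6th-order Butterworth, 0.25 Hz) that attenuates the
    integration-drift component. The series kind advances one step
    (acceleration -> velocity -> displacement).
    """
    if ts.kind not in _INTEGRATES_TO:
        raise ValueError(f"cannot integrate a series of kind {ts.kind!r}")
    from scipy.integrate import cumulative_trapezoid

    raw = cumulative_trapezoid(ts.values, dx=1.0 / ts.sample_rate, initial=0.0)
    integrated = TimeSeries(raw, ts.sample_rate, _INTEGRATES_TO[ts.kind])
    return butterworth_filter(
        integrated, "highpass", order=highpass_order, cutoff_hz=highpass_cutoff_hz,
        zero_phase=zero_phase,
    )


def trapezoid_integral(ts: TimeSeries) -> TimeSeries:
    """Raw cumulative trapezoid integral without drift removal.

    Exposed separately because the drift high-pass is a distinct step; for a
    constant integrand the output is an exact linear ramp.
    """
    if ts.kind not in _INTEGRATES_TO:
        raise ValueError(f"cannot integrate a series of kind {ts.kind!r}")
    from scipy.integrate import cumulative_trapezoid

    raw = cumulative_trapezoid(ts.values, dx=1.0 / ts.sample_rate, initial=0.0)
    return TimeSeries(raw, ts.sample_rate, _INTEGRATES_TO[ts.kind])


def differentiate(ts: TimeSeries) -> TimeSeries:
    """Differentiate acceleration to jerk with central finite differences."""
    if ts.kind != "acceleration":
        raise ValueError(f"differentiate expects acceleration, got {ts.kind!r}")
    if len(ts) < 2:
        raise ValueError("series must contain at least 2 samples to differentiate")
    out = np.gradient(ts.values) * ts.sample_rate
    return TimeSeries(out, ts.sample_rate, "jerk")


def magnitude(axes: Sequence[TimeSeries]) -> TimeSeries:
    """Per-sample Euclidean norm across axis series (2- or 3-axis sensors)."""
    if not axes:
        raise ValueError("magnitude requires at least one axis")
    n = len(axes[0])
    kind = axes[0].kind
    fs = axes[0].sample_rate
    for ax in axes[1:]:
        if len(ax) != n:
            raise ValueError("all axes must have equal length")
        if ax.kind != kind:
            raise ValueError("all axes must share the same kind")
    stacked = np.vstack([ax.values for ax in axes])
    return TimeSeries(np.sqrt((stacked**2).sum(axis=0)), fs, kind)


def segment_by_touch(
    touch: np.ndarray,
    sample_rate: float,
    debounce_ms: float = 100.0,
    recording_id: str | None = None,
) -> SegmentSet:
    """Split a manipulation-task recording at object contact boundaries.

    The binary touch channel (1 = object contact) defines three components:
    reach ``[0, first contact)``, manipulate ``[first contact, last release)``
    and return ``[last release, end)``. Contact gaps shorter than
    ``debounce_ms`` (brief release glitches) are merged into a single
    manipulate interval.
    """
    touch = np.asarray(touch, dtype=float)
    label = f" in recording {recording_id}" if recording_id else ""
    contact = touch > 0.5
    if not contact.any():
        raise SegmentationError(f"no object contact detected in touch channel{label}")
    n = contact.size
    # contact run boundaries as half-open [on, off) intervals
    edges = np.flatnonzero(np.diff(contact.astype(np.int8)))
    ons = list(np.flatnonzero(np.diff(np.r_[0, contact.astype(np.int8)]) == 1))
    offs = list(np.flatnonzero(np.diff(np.r_[contact.astype(np.int8), 0]) == -1) + 1)
    del edges
    # merge gaps shorter than the debounce window
    gap_samples = int(round(debounce_ms / 1000.0 * sample_rate))
    merged: list[tuple[int, int]] = []
    for on, off in zip(ons, offs):
        if merged and on - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    first_on = merged[0][0]
    last_off = merged[-1][1]
    if first_on == 0:
        raise SegmentationError(f"contact begins at the first sample; no reach segment{label}")
    if last_off >= n:
        raise SegmentationError(f"contact persists to the last sample; no return segment{label}")
    return SegmentSet((0, first_on), (first_on, last_off), (last_off, n))
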