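"""Head-movement detection from yaw traces and the main-sequence fit.

The detection procedure mirrors the recording pipeline of a 913.68 Hz HMD
head tracker: first-difference angular velocity, a 10-sample forward moving
average, localisation of the peak-velocity sample, and an outward scan for
the first samples on either side of the peak where the smoothed speed drops
below 3 deg/s. Movements that never exceed 3 deg/s, or whose detected
amplitude is below 10 deg (less than half the 20-deg fixation-to-target
distance), are flagged invalid rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .traces import SampledTrace

__all__ = [
    "VELOCITY_THRESHOLD",
    "MIN_AMPLITUDE",
    "SMOOTHING_WINDOW",
    "HeadMovementEvent",
    "MainSequenceFit",
    "compute_velocity",
    "smooth_velocity",
    "detect_head_movement",
    "fit_main_sequence",
]

#: Onset/offset speed criterion (deg/s) applied to the smoothed velocity.
VELOCITY_THRESHOLD = 3.0
#: Minimum head-movement amplitude (deg); smaller movements are excluded.
MIN_AMPLITUDE = 10.0
#: Forward moving-average window (samples) for velocity smoothing.
SMOOTHING_WINDOW = 10


@dataclass
class HeadMovementEvent:
    """A detected head movement (or the reason none was accepted).

    ``amplitude`` is the unsigned position change between onset and offset;
    ``signed_displacement`` keeps the direction for gain computations.
    ``extra_lobes`` counts additional suprathreshold speed lobes beyond the
    one containing the global peak (a single movement per trial is assumed).
    """

    onset_time: float
    offset_time: float
    peak_velocity: float
    peak_time: float
    amplitude: float
    duration: float  # ms
    valid: bool
    exclusion_reason: str = "none"  # none | below_velocity_threshold | amplitude_below_10deg
    signed_displacement: float = 0.0
    extra_lobes: int = 0
    onset_index: int = 0
    offset_index: int = 0
    peak_index: int = 0


@dataclass
class MainSequenceFit:
    """OLS fit of peak velocity (deg/s) on amplitude (deg) over valid events."""

    slope: float
    intercept: float
    n_events: int
    residual_sd: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, amplitude: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(amplitude, float)


def compute_velocity(trace: SampledTrace) -> np.ndarray:
    """Time-based first-difference velocity, ``(x[i+1]-x[i])/(t[i+1]-t[i])``.

    Length is ``n - 1``; velocity sample ``i`` is attributed to trace sample
    ``i``. Duplicate timestamps raise ``ValueError``. Using the actual
    timestamps (not the nominal rate) keeps the estimate exact for linear
    segments under recorder jitter.
    """
    dt = np.diff(trace.times)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in trace")
    return np.diff(trace.angles) / dt


def smooth_velocity(v: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Forward moving average over ``window`` consecutive velocity samples.

    ``s[i] = mean(v[i : i+window])``. Near the end of the series, where
    fewer than ``window`` samples remain, the window shrinks to the samples
    available (no zero padding, which would fabricate spurious onsets).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity series")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = v.size
    csum = np.concatenate(([0.0], np.cumsum(v)))
    ends = np.minimum(np.arange(n) + window, n)
    counts = ends - np.arange(n)
    return (csum[ends] - csum[:-1]) / counts


def _count_lobes(above: np.ndarray) -> int:
    """Number of contiguous runs of True in a boolean array."""
    if above.size == 0:
        return 0
    a = above.astype(np.int8)
    return int(a[0] + np.sum(np.diff(a) == 1))


def detect_head_movement(
    trace: SampledTrace,
    threshold: float = VELOCITY_THRESHOLD,
    min_amplitude: float = MIN_AMPLITUDE,
    window: int = SMOOTHING_WINDOW,
) -> HeadMovementEvent:
    """Detect the head movement around the global smoothed-speed peak.

    The peak sample is the argmax of the absolute smoothed velocity. Onset is
    the last sample before the peak with smoothed speed below ``threshold``
    (first sample if the speed never drops below it before the peak); offset
    the first such sample after the peak (last sample otherwise). The event
    is invalid with reason ``below_velocity_threshold`` when the speed never
    exceeds the threshold, and ``amplitude_below_10deg`` when the
    onset-to-offset position change is smaller than ``min_amplitude``.
    Degenerate traces yield invalid events, never exceptions.
    """
    v = compute_velocity(trace)
    s = smooth_velocity(v, window=window)
    speed = np.abs(s)
    peak_idx = int(np.argmax(speed))
    peak_speed = float(speed[peak_idx])

    below_before = np.flatnonzero(speed[:peak_idx] < threshold)
    onset_idx = int(below_before[-1]) if below_before.size else 0
    below_after = np.flatnonzero(speed[peak_idx + 1:] < threshold)
    offset_idx = int(peak_idx + 1 + below_after[0]) if below_after.size \
        else speed.size - 1

    disp = float(trace.angles[offset_idx] - trace.angles[onset_idx])
    amplitude = abs(disp)
    onset_t = float(trace.times[onset_idx])
    offset_t = float(trace.times[offset_idx])

    valid = True
    reason = "none"
    if peak_speed <= threshold:
        valid, reason = False, "below_velocity_threshold"
    elif amplitude < min_amplitude:
        valid, reason = False, "amplitude_below_10deg"

    return HeadMovementEvent(
        onset_time=onset_t,
        offset_time=offset_t,
        peak_velocity=peak_speed,
        peak_time=float(trace.times[peak_idx]),
        amplitude=amplitude,
        duration=(offset_t - onset_t) * 1000.0,
        valid=valid,
        exclusion_reason=reason,
        signed_displacement=disp,
        extra_lobes=max(_count_lobes(speed > threshold) - 1, 0),
        onset_index=onset_idx,
        offset_index=offset_idx,
        peak_index=peak_idx,
    )


def fit_main_sequence(events: Sequence[HeadMovementEvent]) -> MainSequenceFit:
    """OLS of peak velocity on amplitude over the valid events.

    Requires at least two valid events with at least two distinct amplitudes.
    Standard errors use the classical homoscedastic formulas (NaN when only
    two points are available).
    """
    valid = [e for e in events if e.valid]
    if len(valid) < 2:
        raise ValueError("need at least two valid events")
    x = np.array([e.amplitude for e in valid])
    y = np.array([e.peak_velocity for e in valid])
    if np.ptp(x) == 0:
        raise ValueError("all amplitudes identical; main sequence undefined")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    n = x.size
    if n > 2:
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
        residual_sd = np.sqrt(s2)
    else:
        slope_se = intercept_se = float("nan")
        residual_sd = 0.0
    return MainSequenceFit(
        slope=float(slope), intercept=float(intercept), n_events=n,
        residual_sd=float(residual_sd), slope_se=float(slope_se),
        intercept_se=float(intercept_se),
    )
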