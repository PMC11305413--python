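"""Timestamped angular-position streams.

A :class:`SampledTrace` is the raw material of every detection stage: a head
yaw trace recorded by the HMD tracker (~913.68 Hz) or a horizontal gaze trace
from the built-in eye tracker (120 Hz). Angles are in rotational degrees,
positive rightward; times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledTrace"]


@dataclass(eq=False)
class SampledTrace:
    """A timestamped angular position stream (head yaw or horizontal gaze).

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing, length >= 2.
    angles : array-like of float
        Angular position in degrees at each sample (positive = rightward).
    nominal_rate : float
        Nominal sampling rate in Hz. Real recorders jitter around it; all
        kinematic computations use the actual timestamps, never this value.
    stream : str
        Stream label, ``"head"`` or ``"gaze"``.
    meta : dict
        Free-form generation metadata (ground truth of synthetic traces).
    """

    times: np.ndarray
    angles: np.ndarray
    nominal_rate: float
    stream: str = "head"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.ndim != 1 or self.angles.ndim != 1:
            raise ValueError("times and angles must be one-dimensional")
        if self.times.size != self.angles.size:
            raise ValueError(
                f"times ({self.times.size}) and angles ({self.angles.size}) "
                "must have equal length"
            )
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Trace span in seconds."""
        return float(self.times[-1] - self.times[0])

    def segment(self, t0: float, t1: float) -> "SampledTrace":
        """Return the sub-trace with times in ``[t0, t1]`` (inclusive)."""
        mask = (self.times >= t0) & (self.times <= t1)
        if mask.sum() < 2:
            raise ValueError(f"fewer than two samples in [{t0}, {t1}]")
        return SampledTrace(
            self.times[mask], self.angles[mask], self.nominal_rate,
            stream=self.stream, meta=dict(self.meta),
        )

    def shifted(self, dt: float) -> "SampledTrace":
        """Return a copy with all timestamps shifted by ``dt`` seconds."""
        return SampledTrace(
            self.times + dt, self.angles.copy(), self.nominal_rate,
            stream=self.stream, meta=dict(self.meta),
        )
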