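"""Saccade detection at 120 Hz and the fixation-during-head-movement metric.

At 120 Hz, velocity-threshold saccade detectors are unreliable, so saccades
are found from amplitude changes between consecutive samples, irrespective of
the time elapsed between them: an onset is the sample immediately preceding a
consecutive-sample difference of at least 1 deg; the matching offset is the
earliest sample recorded at least 30 ms after the onset that deviates less
than 0.1 deg from its predecessor. Detection operates on gaze-in-world
(head + eye-in-head), so vestibulo-ocular counter-rotation of the eye during
a head movement does not register as a saccade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kinematics import HeadMovementEvent
from .traces import SampledTrace

__all__ = [
    "ONSET_DIFF_THRESHOLD",
    "OFFSET_DIFF_THRESHOLD",
    "MIN_SACCADE_DURATION",
    "FIXATION_WINDOW",
    "SaccadeEvent",
    "FixationMetric",
    "detect_saccades",
    "fixation_duration",
    "primary_saccade_amplitude",
    "saccade_amplitude_summary",
]

#: Consecutive-sample difference (deg) marking a saccade onset.
ONSET_DIFF_THRESHOLD = 1.0
#: Consecutive-sample difference (deg) below which a saccade has ended.
OFFSET_DIFF_THRESHOLD = 0.1
#: Minimum onset-to-offset separation (s).
MIN_SACCADE_DURATION = 0.030
#: Half-width (deg) of the "on target" window for the fixation metric,
#: matching the 1-deg fixation-control window around the fixation cross.
FIXATION_WINDOW = 1.0


@dataclass
class SaccadeEvent:
    """A detected saccade; amplitude is signed (offset minus onset position)."""

    onset_time: float
    offset_time: float
    amplitude: float
    onset_index: int
    offset_index: int
    truncated: bool = False  # offset criterion never met; closed at trace end

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass
class FixationMetric:
    """Share of a head movement spent fixating the gaze-shift target."""

    fixation_fraction: float  # percent of head-movement duration
    head_event: HeadMovementEvent
    n_saccades_during: int


def detect_saccades(
    trace: SampledTrace,
    onset_threshold: float = ONSET_DIFF_THRESHOLD,
    offset_threshold: float = OFFSET_DIFF_THRESHOLD,
    min_duration: float = MIN_SACCADE_DURATION,
) -> list[SaccadeEvent]:
    """Detect saccades by the consecutive-sample amplitude-difference rules.

    Scanning resumes after each offset, so events are non-overlapping and
    time-ordered. A trace spanning less than ``min_duration`` yields an empty
    list. If the offset criterion is never met the event closes at the final
    sample and is flagged ``truncated``.
    """
    t = trace.times
    x = trace.angles
    n = t.size
    if t[-1] - t[0] < min_duration:
        return []
    adiff = np.abs(np.diff(x))

    events: list[SaccadeEvent] = []
    i = 0
    while i < n - 1:
        if adiff[i] >= onset_threshold:
            onset = i
            offset: Optional[int] = None
            j = onset + 1
            while j < n:
                if (t[j] - t[onset] >= min_duration
                        and abs(x[j] - x[j - 1]) < offset_threshold):
                    offset = j
                    break
                j += 1
            truncated = offset is None
            if truncated:
                offset = n - 1
            events.append(SaccadeEvent(
                onset_time=float(t[onset]),
                offset_time=float(t[offset]),
                amplitude=float(x[offset] - x[onset]),
                onset_index=onset,
                offset_index=int(offset),
                truncated=truncated,
            ))
            i = int(offset)
        else:
            i += 1
    return events


def fixation_duration(
    gaze: SampledTrace,
    head_event: HeadMovementEvent,
    target_position: float,
    window: float = FIXATION_WINDOW,
    saccades: Optional[Sequence[SaccadeEvent]] = None,
) -> FixationMetric:
    """Fraction of the head movement spent with gaze on the target.

    Time within ``[onset, offset]`` of the head movement counts as fixation
    when the gaze sample lies within ``window`` of ``target_position`` and no
    detected saccade is in progress. Dwell times come from the inter-sample
    intervals of the gaze trace (each interval attributed to its left
    sample), clipped to the head-movement window. A low value means many eye
    movements were made during the head-movement component of the gaze shift.
    """
    if not head_event.valid:
        raise ValueError("head event is not valid")
    t0, t1 = head_event.onset_time, head_event.offset_time
    t = gaze.times
    if not np.any((t >= t0) & (t <= t1)):
        raise ValueError("no gaze samples within the head-movement interval")
    if saccades is None:
        saccades = detect_saccades(gaze)

    in_sacc = np.zeros(t.size, dtype=bool)
    for s in saccades:
        in_sacc |= (t >= s.onset_time) & (t < s.offset_time)
    on_target = np.abs(gaze.angles - target_position) <= window
    fixating = on_target & ~in_sacc

    left = np.clip(t[:-1], t0, t1)
    right = np.clip(t[1:], t0, t1)
    fix_time = float(np.sum((right - left) * fixating[:-1]))

    duration_s = t1 - t0
    frac = 100.0 * fix_time / duration_s if duration_s > 0 else 0.0
    n_during = sum(1 for s in saccades
                   if s.onset_time < t1 and s.offset_time > t0)
    return FixationMetric(
        fixation_fraction=float(np.clip(frac, 0.0, 100.0)),
        head_event=head_event,
        n_saccades_during=n_during,
    )


def primary_saccade_amplitude(events: Sequence[SaccadeEvent]) -> float:
    """Amplitude of the primary (largest-magnitude) saccade of a trial."""
    if len(events) == 0:
        raise ValueError("no saccade detected in trial")
    return max(events, key=lambda e: abs(e.amplitude)).amplitude


def saccade_amplitude_summary(
    events_by_trial: Mapping[int, Sequence[SaccadeEvent]],
) -> pd.DataFrame:
    """Per-trial primary-saccade amplitudes.

    Trials without any detected saccade are flagged missing and carry NaN;
    they are excluded from amplitude means downstream.
    """
    rows = []
    for trial, events in events_by_trial.items():
        if len(events) == 0:
            rows.append({"trial": trial, "amplitude": np.nan, "missing": True})
        else:
            rows.append({
                "trial": trial,
                "amplitude": primary_saccade_amplitude(events),
                "missing": False,
            })
    return pd.DataFrame(rows).set_index("trial")
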