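"""Delimited-text readers and writers for traces and trial tables.

Traces: CSV with header ``time_s,angle_deg,stream`` (stream in {head, gaze});
several streams may share one file. Trial tables: CSV with header
``trial,gaze_mode,target_presentation,background,gain,comparison_deg,response``
(response in {left, right} or empty before simulation). Malformed rows raise
``ValueError`` naming the offending line number; round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .synthetic import TrialRecord
from .traces import SampledTrace

__all__ = [
    "TRACE_COLUMNS",
    "TRIAL_COLUMNS",
    "write_traces",
    "read_traces",
    "write_trials",
    "read_trials",
]

TRACE_COLUMNS = ["time_s", "angle_deg", "stream"]
TRIAL_COLUMNS = ["trial", "gaze_mode", "target_presentation", "background",
                 "gain", "comparison_deg", "response"]


def _require_numeric(frame: pd.DataFrame, column: str, path: Path,
                     allow_blank: bool = False) -> pd.Series:
    raw = frame[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if allow_blank:
        bad &= raw.notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"'{column}' at line {line}")
    return values


def write_traces(path: Union[str, Path],
                 traces: Union[SampledTrace, Mapping[str, SampledTrace],
                               Sequence[SampledTrace]]) -> None:
    """Write one or several traces to a delimited text file."""
    if isinstance(traces, SampledTrace):
        traces = [traces]
    elif isinstance(traces, Mapping):
        traces = list(traces.values())
    frames = [pd.DataFrame({"time_s": tr.times, "angle_deg": tr.angles,
                            "stream": tr.stream}) for tr in traces]
    # no float_format: pandas writes shortest round-trippable representations
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: Union[str, Path]) -> dict[str, SampledTrace]:
    """Read traces from a delimited text file, one per stream label.

    The nominal rate is recovered as the reciprocal median sampling step.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"stream": str},
                        float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing header column(s) {missing}")
    times = _require_numeric(frame, "time_s", path)
    angles = _require_numeric(frame, "angle_deg", path)
    out: dict[str, SampledTrace] = {}
    for stream in frame["stream"].unique():
        mask = (frame["stream"] == stream).to_numpy()
        t = times.to_numpy()[mask]
        a = angles.to_numpy()[mask]
        rate = 1.0 / float(np.median(np.diff(t)))
        out[str(stream)] = SampledTrace(t, a, rate, stream=str(stream))
    return out


def write_trials(path: Union[str, Path],
                 trials: Iterable[TrialRecord]) -> None:
    """Write a trial table; unanswered trials get an empty response field."""
    trials = list(trials)
    frame = pd.DataFrame({
        "trial": [t.trial for t in trials],
        "gaze_mode": [t.gaze_mode for t in trials],
        "target_presentation": [t.target_presentation for t in trials],
        "background": [t.background for t in trials],
        "gain": [t.gain for t in trials],
        "comparison_deg": [t.comparison_deg for t in trials],
        "response": [t.response if t.response is not None else ""
                     for t in trials],
    })
    if any(t.subject is not None for t in trials):
        frame.insert(0, "subject", [t.subject for t in trials])
    frame.to_csv(path, index=False)


def read_trials(path: Union[str, Path]) -> list[TrialRecord]:
    """Read a trial table back into :class:`TrialRecord` objects."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"response": str},
                        float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing header column(s) {missing}")
    comparison = _require_numeric(frame, "comparison_deg", path)
    gain = _require_numeric(frame, "gain", path)
    trial_no = _require_numeric(frame, "trial", path)

    records = []
    for i in frame.index:
        resp = frame.loc[i, "response"]
        resp = None if (pd.isna(resp) or resp == "") else str(resp)
        if resp not in (None, "left", "right"):
            raise ValueError(
                f"{path}: invalid response {resp!r} at line {int(i) + 2}")
        records.append(TrialRecord(
            trial=int(trial_no[i]),
            comparison_deg=float(comparison[i]),
            gaze_mode=str(frame.loc[i, "gaze_mode"]),
            target_presentation=str(frame.loc[i, "target_presentation"]),
            background=str(frame.loc[i, "background"]),
            gain=float(gain[i]),
            response=resp,
            subject=(str(frame.loc[i, "subject"])
                     if "subject" in frame.columns else None),
        ))
    return records
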