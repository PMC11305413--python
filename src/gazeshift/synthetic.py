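"""Seeded synthetic head/eye traces, trial schedules, and 2AFC responses.

This module generates data with the statistical structure the downstream
analysis assumes, so every stage can be exercised against known ground truth:

* head yaw movements whose peak velocity follows the head-movement main
  sequence ``v_peak = intercept + slope * amplitude`` with a raised-cosine
  velocity profile;
* gaze-in-world traces with a primary saccade that precedes the head movement
  and (in sequential mode) perfect vestibulo-ocular stabilization of gaze on
  the target during the head rotation;
* balanced 7-level comparison-stimulus schedules (+/-1.37 deg in 0.46-deg
  steps, 8 repetitions -> 56 trials per session);
* two-alternative forced-choice responses from a cumulative-Gaussian observer
  with configurable point of horizontal alignment (PHA) and just-noticeable
  difference (JND).

All randomness flows through one explicit seed per generated artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .traces import SampledTrace

__all__ = [
    "MAIN_SEQUENCE_INTERCEPT",
    "MAIN_SEQUENCE_SLOPE",
    "COMPARISON_POSITIONS",
    "HEAD_SAMPLE_RATE",
    "EYE_SAMPLE_RATE",
    "ObserverSpec",
    "HeadMovementSpec",
    "TrialScheduleSpec",
    "GazeShiftScenario",
    "TrialRecord",
    "generate_head_trace",
    "generate_gaze_trace",
    "generate_trial_schedule",
    "simulate_responses",
    "response_probability",
    "apply_velocity_gain",
]

#: Head-movement main-sequence line (peak velocity in deg/s as a function of
#: amplitude in deg) pooled across trials and participants.
MAIN_SEQUENCE_INTERCEPT = 13.22
MAIN_SEQUENCE_SLOPE = 1.27

#: The seven comparison-stimulus offsets (deg); negative = leftward shift.
COMPARISON_POSITIONS = (-1.37, -0.92, -0.46, 0.0, 0.46, 0.92, 1.37)

#: Default recorder rates (Hz): HMD head tracker and built-in eye tracker.
HEAD_SAMPLE_RATE = 913.68
EYE_SAMPLE_RATE = 120.0


@dataclass(frozen=True)
class ObserverSpec:
    """Generating parameters of a cumulative-Gaussian 2AFC observer.

    ``pha`` is the true point of horizontal alignment (the 50% point of the
    psychometric function, deg); ``jnd`` the true discrimination threshold
    (deg, > 0, equal to the Gaussian sigma under the package's JND
    convention); ``lapse_rate`` a stimulus-independent guessing probability.
    """

    pha: float
    jnd: float
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.jnd > 0:
            raise ValueError("jnd must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")


@dataclass(frozen=True)
class HeadMovementSpec:
    """Kinematic parameters of one synthetic head movement.

    Peak velocity is drawn from the main sequence,
    ``ms_intercept + ms_slope * amplitude + N(0, velocity_noise_sd)``,
    truncated to be positive. ``position_noise_sd`` is the RMS of the
    tracker's position noise; it is low-pass filtered (100 ms window) before
    being added, emulating the slowly varying jitter of an HMD tracker rather
    than white sensor noise.
    """

    amplitude: float
    ms_intercept: float = MAIN_SEQUENCE_INTERCEPT
    ms_slope: float = MAIN_SEQUENCE_SLOPE
    velocity_noise_sd: float = 0.0
    sample_rate: float = HEAD_SAMPLE_RATE
    direction: int = 1
    position_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")

    def peak_velocity(self, noise: float = 0.0) -> float:
        """Main-sequence peak velocity (deg/s) for this amplitude."""
        v = self.ms_intercept + self.ms_slope * self.amplitude + noise
        return max(v, 1e-6)

    def movement_duration(self, noise: float = 0.0) -> float:
        """Raised-cosine movement duration ``2 * amplitude / v_peak`` (s)."""
        if self.amplitude <= 0:
            return 0.0
        return 2.0 * self.amplitude / self.peak_velocity(noise)


@dataclass(frozen=True)
class TrialScheduleSpec:
    """Comparison-stimulus schedule for one session."""

    comparison_positions: Sequence[float] = COMPARISON_POSITIONS
    repetitions_per_position: int = 8
    randomize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positions = tuple(float(p) for p in self.comparison_positions)
        object.__setattr__(self, "comparison_positions", positions)
        if len(positions) == 0:
            raise ValueError("comparison_positions must be non-empty")
        if len(set(positions)) != len(positions):
            raise ValueError("comparison_positions must be unique")
        if self.repetitions_per_position < 1:
            raise ValueError("repetitions_per_position must be >= 1")

    @property
    def n_trials(self) -> int:
        return len(self.comparison_positions) * self.repetitions_per_position


@dataclass(frozen=True)
class GazeShiftScenario:
    """Geometry and condition of one gaze-shift trial.

    The fixation cross sits at ``fixation_eccentricity`` (default -10 deg,
    left of straight ahead) and the gaze-shift target at
    ``target_eccentricity`` (+10 deg), so the required gaze shift spans 20
    deg. ``visual_velocity_gain`` scales the background-grating displacement
    opposite to the head movement (1.0 = background moves exactly as fast as
    the head).
    """

    gaze_mode: str = "unrestricted"
    target_presentation: str = "stationary"
    background: str = "none"
    visual_velocity_gain: float = 1.0
    fixation_eccentricity: float = -10.0
    target_eccentricity: float = 10.0

    GAIN_PRESETS = (1.0, 1.15, 1.3)

    def __post_init__(self) -> None:
        if self.gaze_mode not in ("unrestricted", "sequential"):
            raise ValueError("gaze_mode must be 'unrestricted' or 'sequential'")
        if self.target_presentation not in ("stationary", "flashed"):
            raise ValueError(
                "target_presentation must be 'stationary' or 'flashed'")
        if self.background not in ("grating", "none"):
            raise ValueError("background must be 'grating' or 'none'")
        if self.visual_velocity_gain < 1.0:
            raise ValueError("visual_velocity_gain must be >= 1")


@dataclass
class TrialRecord:
    """One 2AFC trial: condition labels, comparison offset, response."""

    trial: int
    comparison_deg: float
    gaze_mode: str = "unrestricted"
    target_presentation: str = "stationary"
    background: str = "none"
    gain: float = 1.0
    response: Optional[str] = None  # "left" | "right" | None
    subject: Optional[str] = None
    meta: dict = field(default_factory=dict)


def _lowpass_noise(n: int, sd: float, rate: float, rng: np.random.Generator,
                   window_s: float = 0.1) -> np.ndarray:
    """Gaussian noise low-pass filtered by a moving average, rescaled to RMS ``sd``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    w = max(int(round(window_s * rate)), 1)
    white = rng.standard_normal(n + w - 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(white, kernel, mode="valid")
    # moving average of unit-variance white noise has variance 1/w
    return smooth * (sd * math.sqrt(w))


def generate_head_trace(
    spec: HeadMovementSpec,
    duration: float = 2.5,
    onset_time: float = 0.5,
    seed: Optional[int] = None,
    start_angle: float = 0.0,
) -> SampledTrace:
    """Generate a yaw trace containing one raised-cosine head movement.

    The angular velocity follows ``v(t) = v_peak/2 * (1 - cos(2*pi*t/D))``
    for ``t`` in ``[0, D]`` with ``D = 2*amplitude/v_peak``, i.e. a smooth
    bell whose time integral is exactly the movement amplitude. Before the
    onset the trace sits at ``start_angle``; after the offset at
    ``start_angle + direction * amplitude``. Tracker noise (see
    :class:`HeadMovementSpec`) is added on top.

    A zero (or zero-direction) amplitude yields a degenerate flat trace. A
    movement that does not fit within ``duration`` raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * spec.sample_rate))
    if n < 2:
        raise ValueError("duration too short for the requested sample rate")
    times = np.arange(n) / spec.sample_rate

    amp = spec.amplitude if spec.direction != 0 else 0.0
    meta: dict = {"spec": spec, "onset_time": onset_time}
    if amp <= 0:
        angles = np.full(n, start_angle)
        meta.update(peak_velocity=0.0, movement_duration=0.0, amplitude=0.0)
    else:
        noise = rng.normal(0.0, spec.velocity_noise_sd) \
            if spec.velocity_noise_sd > 0 else 0.0
        v_peak = spec.peak_velocity(noise)
        move_dur = 2.0 * amp / v_peak
        if onset_time < 0 or onset_time + move_dur > duration:
            raise ValueError(
                f"movement of {move_dur:.3f} s starting at {onset_time:.3f} s "
                f"does not fit in a {duration:.3f} s trace"
            )
        u = np.clip((times - onset_time) / move_dur, 0.0, 1.0)
        angles = start_angle + spec.direction * amp * (
            u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi))
        meta.update(peak_velocity=v_peak, movement_duration=move_dur,
                    amplitude=amp, offset_time=onset_time + move_dur)

    angles = angles + _lowpass_noise(n, spec.position_noise_sd,
                                     spec.sample_rate, rng)
    return SampledTrace(times, angles, spec.sample_rate, stream="head",
                        meta=meta)


def generate_gaze_trace(
    scenario: GazeShiftScenario,
    head_trace: SampledTrace,
    saccade_amplitude: float,
    seed: Optional[int] = None,
    sample_rate: float = EYE_SAMPLE_RATE,
    n_secondary_saccades: int = 0,
    secondary_amplitude: float = 2.0,
    noise_sd: float = 0.1,
) -> SampledTrace:
    """Generate a gaze-in-world trace matching a head trace.

    The eye performs a rapid primary saccade of ``saccade_amplitude`` from the
    fixation cross toward the target shortly before the head-movement onset,
    then holds gaze on the landing position throughout the head rotation
    (perfect vestibulo-ocular counter-rotation). In ``unrestricted`` mode,
    ``n_secondary_saccades`` small saccades are injected during the head
    movement: each is a one-sample step of ``secondary_amplitude`` away from
    the landing position followed by a slow (< 0.1 deg/sample) glide back, so
    each injection registers as exactly one event under the 1-deg onset /
    0.1-deg offset detection rules while lowering the fixation fraction.

    Ground truth (primary/secondary saccade times and amplitudes, landing
    position) is stored in ``trace.meta``.
    """
    if sample_rate > head_trace.nominal_rate:
        raise ValueError("eye sample rate must not exceed the head sample rate")
    required_dir = math.copysign(
        1.0, scenario.target_eccentricity - scenario.fixation_eccentricity)
    if saccade_amplitude * required_dir <= 0:
        raise ValueError(
            "saccade amplitude sign inconsistent with the target direction")
    if scenario.gaze_mode == "sequential" and n_secondary_saccades:
        raise ValueError("sequential mode admits no secondary saccades")

    rng = np.random.default_rng(seed)
    t0, t1 = head_trace.times[0], head_trace.times[-1]
    n = int(round((t1 - t0) * sample_rate)) + 1
    times = t0 + np.arange(n) / sample_rate

    head_onset = head_trace.meta.get("onset_time", t0 + 0.4 * (t1 - t0))
    head_offset = head_trace.meta.get(
        "offset_time", head_onset + 0.2 * (t1 - t0))

    landing = scenario.fixation_eccentricity + saccade_amplitude
    # primary saccade: 25 ms ramp ending 100 ms before the head starts moving
    sacc_dur = 0.025
    sacc_on = max(head_onset - 0.1 - sacc_dur, t0)
    u = np.clip((times - sacc_on) / sacc_dur, 0.0, 1.0)
    gaze = scenario.fixation_eccentricity + saccade_amplitude * u

    primary = {"onset_time": sacc_on, "amplitude": saccade_amplitude}
    secondary: list[dict] = []
    if n_secondary_saccades > 0:
        glide_step = 0.08  # deg/sample, below the 0.1-deg offset criterion
        glide_dur = abs(secondary_amplitude) / glide_step / sample_rate
        span = head_offset - head_onset
        starts = head_onset + span * (
            np.arange(1, n_secondary_saccades + 1)
            / (n_secondary_saccades + 1.0)) - glide_dur / 2.0
        for s in starts:
            step_mask = times >= s
            # one-sample step away from the target, slow linear return
            back = np.clip((times - s) * sample_rate * glide_step,
                           0.0, abs(secondary_amplitude))
            excursion = np.where(step_mask,
                                 abs(secondary_amplitude) - back, 0.0)
            gaze = gaze - np.sign(saccade_amplitude) * excursion
            secondary.append({"onset_time": float(s),
                              "amplitude": -np.sign(saccade_amplitude)
                              * abs(secondary_amplitude)})

    if noise_sd > 0:
        gaze = gaze + rng.normal(0.0, noise_sd, n)

    meta = {
        "scenario": scenario,
        "primary_saccade": primary,
        "secondary_saccades": secondary,
        "landing_position": landing,
        "head_onset_time": head_onset,
        "head_offset_time": head_offset,
    }
    return SampledTrace(times, gaze, sample_rate, stream="gaze", meta=meta)


def generate_trial_schedule(
    spec: TrialScheduleSpec,
    *,
    gaze_mode: str = "unrestricted",
    target_presentation: str = "stationary",
    background: str = "none",
    gain: float = 1.0,
    subject: Optional[str] = None,
) -> list[TrialRecord]:
    """Build a balanced trial schedule for one session.

    Every comparison position appears exactly ``repetitions_per_position``
    times; with the default 7 positions x 8 repetitions this gives the 56
    trials of one session. When ``spec.randomize`` is set the order is a
    seeded permutation.
    """
    positions = np.repeat(spec.comparison_positions,
                          spec.repetitions_per_position)
    if spec.randomize:
        rng = np.random.default_rng(spec.seed)
        positions = rng.permutation(positions)
    return [
        TrialRecord(
            trial=i,
            comparison_deg=float(x),
            gaze_mode=gaze_mode,
            target_presentation=target_presentation,
            background=background,
            gain=gain,
            subject=subject,
        )
        for i, x in enumerate(positions)
    ]


def response_probability(x: float | np.ndarray,
                         observer: ObserverSpec) -> float | np.ndarray:
    """Probability of a "right" response at comparison offset ``x``.

    ``p = lapse/2 + (1 - lapse) * Phi((x - pha) / sigma)`` with
    ``sigma = jnd`` (the package's JND convention). At ``x = pha`` and zero
    lapse this is exactly 0.5, the definition of the point of subjective
    equality.
    """
    lam = observer.lapse_rate
    p = norm.cdf((np.asarray(x, dtype=float) - observer.pha) / observer.jnd)
    out = lam / 2.0 + (1.0 - lam) * p
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def simulate_responses(
    schedule: Sequence[TrialRecord],
    observer: ObserverSpec,
    seed: Optional[int] = None,
) -> list[TrialRecord]:
    """Draw seeded Bernoulli 2AFC responses for every trial in a schedule.

    Returns new records; the input schedule is not mutated.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in schedule:
        p = response_probability(rec.comparison_deg, observer)
        resp = "right" if rng.random() < p else "left"
        out.append(replace(rec, response=resp))
    return out


def apply_velocity_gain(head_amplitude: float, gain: float,
                        direction: int = 1) -> float:
    """Signed background displacement produced by a gained head movement.

    The grating moves against the head: the returned displacement is
    ``-direction * gain * head_amplitude``. E.g. a 20-deg rightward head
    movement under gain 1.15 shifts the background 23 deg to the left.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    return -direction * gain * head_amplitude
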