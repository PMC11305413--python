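"""Ground-truth recovery studies used for validation.

These routines exercise whole analysis chains on synthetic data with known
generating parameters and quantify how well the chain recovers them:

* :func:`main_sequence_recovery` — raised-cosine head movements with
  main-sequence peak velocities plus Gaussian scatter, run through velocity
  computation, smoothing, onset/offset detection and the amplitude exclusion,
  then summarised by the OLS main-sequence fit;
* :func:`psychometric_recovery` — repeated simulate-and-refit replicates of
  the cumulative-Gaussian observer, reporting the mean recovered location and
  spread (bias study).

Both are deterministic given their seed and are reused by the test suite and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import (
    HeadMovementEvent,
    MainSequenceFit,
    detect_head_movement,
    fit_main_sequence,
)
from .psychometrics import PsychometricModel, ResponseTable
from .synthetic import (
    COMPARISON_POSITIONS,
    MAIN_SEQUENCE_INTERCEPT,
    MAIN_SEQUENCE_SLOPE,
    HeadMovementSpec,
    ObserverSpec,
    response_probability,
)
from .synthetic import generate_head_trace

__all__ = [
    "MainSequenceRecovery",
    "PsychometricRecovery",
    "main_sequence_recovery",
    "psychometric_recovery",
]


@dataclass
class MainSequenceRecovery:
    """Detected-event main-sequence fit from a seeded simulation."""

    fit: MainSequenceFit
    events: list[HeadMovementEvent]
    true_slope: float
    true_intercept: float
    n_traces: int


@dataclass
class PsychometricRecovery:
    """Mean recovered (mu, sigma) over seeded refit replicates."""

    mean_mu: float
    mean_sigma: float
    true_mu: float
    true_sigma: float
    n_replicates: int

    @property
    def mu_bias(self) -> float:
        return self.mean_mu - self.true_mu

    @property
    def sigma_bias(self) -> float:
        return self.mean_sigma - self.true_sigma


def main_sequence_recovery(
    n_traces: int = 500,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (10.0, 30.0),
    velocity_noise_sd: float = 3.0,
    intercept: float = MAIN_SEQUENCE_INTERCEPT,
    slope: float = MAIN_SEQUENCE_SLOPE,
    sample_rate: float = 913.68,
) -> MainSequenceRecovery:
    """Recover the main-sequence line through the full detection pipeline.

    Amplitudes are uniform on ``amplitude_range``; each trace's generating
    peak velocity is ``intercept + slope * amplitude + N(0,
    velocity_noise_sd)``. Traces are noiseless in position so the scatter
    around the fitted line reflects only the generating velocity noise and
    detection discretisation.
    """
    rng = np.random.default_rng(seed)
    events: list[HeadMovementEvent] = []
    for _ in range(n_traces):
        amp = float(rng.uniform(*amplitude_range))
        spec = HeadMovementSpec(
            amplitude=amp, ms_intercept=intercept, ms_slope=slope,
            velocity_noise_sd=velocity_noise_sd, sample_rate=sample_rate,
            position_noise_sd=0.0)
        v_floor = max(intercept + slope * amp
                      - 6.0 * max(velocity_noise_sd, 1e-9), 5.0)
        duration = 0.3 + 2.0 * amp / v_floor + 0.2
        trace = generate_head_trace(
            spec, duration=duration, onset_time=0.3,
            seed=int(rng.integers(2 ** 31)))
        events.append(detect_head_movement(trace))
    fit = fit_main_sequence([e for e in events if e.valid])
    return MainSequenceRecovery(fit=fit, events=events, true_slope=slope,
                                true_intercept=intercept, n_traces=n_traces)


def psychometric_recovery(
    n_replicates: int = 200,
    mu: float = 0.1,
    sigma: float = 0.8,
    n_per_position: int = 64,
    positions: tuple[float, ...] = COMPARISON_POSITIONS,
    seed: int = 0,
) -> PsychometricRecovery:
    """Simulate-and-refit bias study of the psychometric MLE.

    Each replicate draws binomial counts at the seven comparison positions
    from the generating observer and refits; the mean recovered parameters
    estimate the finite-sample bias of the estimator at the study's trial
    counts.
    """
    rng = np.random.default_rng(seed)
    observer = ObserverSpec(pha=mu, jnd=sigma)
    xs = np.asarray(positions, dtype=float)
    p_true = np.asarray(response_probability(xs, observer), dtype=float)
    mus, sigmas = [], []
    for _ in range(n_replicates):
        n_right = rng.binomial(n_per_position, p_true)
        table = ResponseTable(xs, n_right,
                              np.full(xs.size, n_per_position))
        fit = PsychometricModel(table).fit()
        if fit.converged:
            mus.append(fit.pha)
            sigmas.append(fit.sigma)
    return PsychometricRecovery(
        mean_mu=float(np.mean(mus)), mean_sigma=float(np.mean(sigmas)),
        true_mu=mu, true_sigma=sigma, n_replicates=len(mus))
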