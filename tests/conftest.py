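import numpy as np
import pytest

from gazeshift import (
    GazeShiftScenario,
    HeadMovementSpec,
    generate_gaze_trace,
    generate_head_trace,
)


@pytest.fixture
def clean_20deg_trace():
    """Noiseless 20-deg raised-cosine head movement at the default rate."""
    spec = HeadMovementSpec(amplitude=20.0, velocity_noise_sd=0.0,
                            position_noise_sd=0.0)
    return generate_head_trace(spec, duration=2.5, onset_time=0.5, seed=0)


@pytest.fixture
def sequential_gaze(clean_20deg_trace):
    """Noiseless sequential-mode gaze trace locked on the target."""
    scenario = GazeShiftScenario(gaze_mode="sequential")
    return generate_gaze_trace(scenario, clean_20deg_trace,
                               saccade_amplitude=20.0, seed=0, noise_sd=0.0)


def random_head_trace(rng, min_len=60, max_len=10_000):
    """A random yaw trace: flat, pure-noise, or movement-plus-noise."""
    kind = rng.integers(3)
    n = int(rng.integers(min_len, max_len))
    rate = 913.68
    times = np.arange(n) / rate
    if kind == 0:
        angles = np.full(n, float(rng.normal(0, 5)))
    elif kind == 1:
        angles = np.cumsum(rng.normal(0, rng.uniform(0.001, 0.02), n))
    else:
        amp = float(rng.uniform(2, 30))
        dur = float(rng.uniform(0.2, 0.8) * times[-1])
        onset = float(rng.uniform(0, times[-1] - dur))
        u = np.clip((times - onset) / dur, 0, 1)
        angles = amp * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        angles = angles + rng.normal(0, rng.uniform(0, 0.01), n)
    return times, angles


def random_gaze_trace(rng, min_len=30, max_len=2_000):
    """A random 120 Hz gaze trace with occasional step-like jumps."""
    n = int(rng.integers(min_len, max_len))
    times = np.arange(n) / 120.0
    angles = rng.normal(0, rng.uniform(0.02, 0.3), n).cumsum() * 0.1
    for _ in range(int(rng.integers(0, 6))):
        at = int(rng.integers(1, n))
        angles[at:] += rng.normal(0, 4)
    return times, angles
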