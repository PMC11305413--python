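"""Generator module: kinematic fidelity, schedule balance, observer model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeshift import (
    GazeShiftScenario,
    HeadMovementSpec,
    ObserverSpec,
    TrialScheduleSpec,
    apply_velocity_gain,
    detect_head_movement,
    detect_saccades,
    generate_gaze_trace,
    generate_head_trace,
    generate_trial_schedule,
    response_probability,
    simulate_responses,
)
from oracles import normal_cdf_by_quadrature


class TestHeadTrace:
    def test_main_sequence_arithmetic(self):
        # 20 deg with the default coefficients: v_peak = 13.22 + 1.27*20
        spec = HeadMovementSpec(amplitude=20.0, velocity_noise_sd=0.0)
        assert spec.peak_velocity() == pytest.approx(38.62)
        assert spec.movement_duration() == pytest.approx(2 * 20 / 38.62,
                                                         abs=1e-12)
        assert spec.movement_duration() == pytest.approx(1.036, abs=5e-4)

    def test_zero_amplitude_is_flat(self):
        spec = HeadMovementSpec(amplitude=0.0, position_noise_sd=0.0)
        trace = generate_head_trace(spec, seed=0)
        assert np.ptp(trace.angles) == 0.0
        assert np.max(np.abs(np.diff(trace.angles))) == 0.0

    def test_raised_cosine_displacement_integrates_to_amplitude(self):
        # trapezoidal integration of the analytic velocity profile
        spec = HeadMovementSpec(amplitude=20.0, velocity_noise_sd=0.0)
        v_peak = spec.peak_velocity()
        dur = spec.movement_duration()
        t = np.linspace(0.0, dur, 200_001)
        v = v_peak / 2.0 * (1.0 - np.cos(2.0 * np.pi * t / dur))
        assert np.trapezoid(v, t) == pytest.approx(20.0, abs=1e-6)
        # and the generated trace traverses exactly that displacement
        trace = generate_head_trace(
            HeadMovementSpec(amplitude=20.0, velocity_noise_sd=0.0,
                             position_noise_sd=0.0), seed=0)
        assert trace.angles[-1] - trace.angles[0] == pytest.approx(20.0,
                                                                   abs=1e-9)

    def test_movement_longer_than_trace_errors(self):
        spec = HeadMovementSpec(amplitude=30.0, velocity_noise_sd=0.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_head_trace(spec, duration=1.0, onset_time=0.5)

    @pytest.mark.parametrize("amplitude", [12.0, 18.0, 24.0, 30.0])
    def test_main_sequence_fidelity_noiseless(self, amplitude):
        # with zero velocity noise, detected (amplitude, peak velocity)
        # lie on the generating line within discretisation error
        spec = HeadMovementSpec(amplitude=amplitude, velocity_noise_sd=0.0,
                                position_noise_sd=0.0)
        trace = generate_head_trace(spec, duration=3.5, onset_time=0.5,
                                    seed=0)
        event = detect_head_movement(trace)
        expected_v = 13.22 + 1.27 * amplitude
        assert event.valid
        assert event.peak_velocity == pytest.approx(expected_v, abs=0.5)
        assert amplitude - 0.5 <= event.amplitude <= amplitude + 1e-9

    def test_seed_determinism(self):
        spec = HeadMovementSpec(amplitude=20.0, velocity_noise_sd=3.0,
                                position_noise_sd=0.02)
        a = generate_head_trace(spec, seed=42)
        b = generate_head_trace(spec, seed=42)
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.times, b.times)


class TestGazeTrace:
    def test_sequential_mode_perfect_vor(self, clean_20deg_trace,
                                         sequential_gaze):
        # gaze during the head movement stays on the target (noiseless)
        meta = sequential_gaze.meta
        during = ((sequential_gaze.times >= meta["head_onset_time"])
                  & (sequential_gaze.times <= meta["head_offset_time"]))
        assert np.allclose(sequential_gaze.angles[during], 10.0, atol=1e-9)

    def test_undershoot_construction(self, clean_20deg_trace):
        scenario = GazeShiftScenario(gaze_mode="sequential")
        gaze = generate_gaze_trace(scenario, clean_20deg_trace,
                                   saccade_amplitude=18.0, seed=0,
                                   noise_sd=0.0)
        # terminal gaze before the head movement undershoots +10 by 2 deg
        pre_head = gaze.times < gaze.meta["head_onset_time"]
        assert gaze.angles[pre_head][-1] == pytest.approx(8.0, abs=1e-9)

    def test_secondary_saccades_detected(self, clean_20deg_trace):
        scenario = GazeShiftScenario(gaze_mode="unrestricted")
        gaze = generate_gaze_trace(scenario, clean_20deg_trace,
                                   saccade_amplitude=20.0, seed=0,
                                   n_secondary_saccades=2,
                                   secondary_amplitude=2.0, noise_sd=0.0)
        events = detect_saccades(gaze)
        assert len(events) == 3  # 1 primary + 2 injected
        assert abs(events[0].amplitude) > abs(events[1].amplitude)

    def test_wrong_saccade_direction_errors(self, clean_20deg_trace):
        scenario = GazeShiftScenario()
        with pytest.raises(ValueError, match="sign inconsistent"):
            generate_gaze_trace(scenario, clean_20deg_trace,
                                saccade_amplitude=-18.0, seed=0)

    def test_eye_rate_must_not_exceed_head_rate(self, clean_20deg_trace):
        scenario = GazeShiftScenario()
        with pytest.raises(ValueError, match="sample rate"):
            generate_gaze_trace(scenario, clean_20deg_trace, 18.0,
                                sample_rate=2000.0)


class TestSchedule:
    def test_default_session_has_56_trials(self):
        schedule = generate_trial_schedule(TrialScheduleSpec(seed=1))
        assert len(schedule) == 56
        positions = [t.comparison_deg for t in schedule]
        for p in (-1.37, -0.92, -0.46, 0.0, 0.46, 0.92, 1.37):
            assert positions.count(p) == 8

    def test_single_position_single_repetition(self):
        spec = TrialScheduleSpec(comparison_positions=[0.46],
                                 repetitions_per_position=1, randomize=False)
        schedule = generate_trial_schedule(spec)
        assert len(schedule) == 1
        assert schedule[0].comparison_deg == 0.46

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1),
           reps=st.integers(1, 12))
    def test_balance_for_any_seed(self, seed, reps):
        spec = TrialScheduleSpec(repetitions_per_position=reps, seed=seed)
        schedule = generate_trial_schedule(spec)
        positions = sorted(t.comparison_deg for t in schedule)
        expected = sorted(
            list(spec.comparison_positions) * reps)
        assert positions == expected

    def test_empty_positions_error(self):
        with pytest.raises(ValueError):
            TrialScheduleSpec(comparison_positions=[])


class TestObserver:
    def test_probability_half_at_pha(self):
        obs = ObserverSpec(pha=0.3, jnd=0.5)
        assert response_probability(0.3, obs) == pytest.approx(0.5)

    def test_probability_matches_normal_cdf_quadrature(self):
        # pha 0, sigma 0.5, x = 1.37 -> Phi(2.74), checked by integration
        obs = ObserverSpec(pha=0.0, jnd=0.5)
        expected = normal_cdf_by_quadrature(2.74)
        assert expected == pytest.approx(0.9969, abs=1e-4)
        assert response_probability(1.37, obs) == pytest.approx(expected,
                                                                abs=1e-6)

    def test_lapse_floor(self):
        obs = ObserverSpec(pha=0.0, jnd=0.5, lapse_rate=0.1)
        assert response_probability(-1e9, obs) == pytest.approx(0.05)
        assert response_probability(1e9, obs) == pytest.approx(0.95)

    def test_response_rate_convergence(self):
        # empirical P(right) approaches the model probability (binomial SE)
        obs = ObserverSpec(pha=0.24, jnd=0.76)
        spec = TrialScheduleSpec(repetitions_per_position=400, seed=0)
        trials = simulate_responses(generate_trial_schedule(spec), obs,
                                    seed=123)
        for x in spec.comparison_positions:
            hits = [t.response == "right" for t in trials
                    if t.comparison_deg == x]
            p_hat = np.mean(hits)
            p = response_probability(x, obs)
            se = np.sqrt(p * (1 - p) / len(hits))
            assert abs(p_hat - p) < 4 * se + 1e-9

    def test_simulation_is_seeded(self):
        obs = ObserverSpec(pha=0.0, jnd=0.8)
        schedule = generate_trial_schedule(TrialScheduleSpec(seed=5))
        a = simulate_responses(schedule, obs, seed=9)
        b = simulate_responses(schedule, obs, seed=9)
        assert [t.response for t in a] == [t.response for t in b]

    def test_invalid_observer_specs(self):
        with pytest.raises(ValueError):
            ObserverSpec(pha=0.0, jnd=0.0)
        with pytest.raises(ValueError):
            ObserverSpec(pha=0.0, jnd=1.0, lapse_rate=0.2)


class TestVelocityGain:
    def test_worked_example(self):
        # 20-deg rightward head movement, gain 1.15 -> 23 deg leftward
        assert apply_velocity_gain(20.0, 1.15, 1) == pytest.approx(-23.0)

    def test_unity_gain(self):
        assert apply_velocity_gain(20.0, 1.0, 1) == pytest.approx(-20.0)

    def test_no_movement(self):
        assert apply_velocity_gain(0.0, 1.3, 1) == 0.0

    def test_opposes_head_direction(self):
        assert apply_velocity_gain(10.0, 1.3, -1) == pytest.approx(13.0)
        with pytest.raises(ValueError):
            apply_velocity_gain(10.0, -0.5, 1)
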