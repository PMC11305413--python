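"""End-to-end orchestration: simulate -> detect -> fit -> stats.

A :func:`run_experiment` call reproduces one of the three study designs on
synthetic observers:

* experiment 1 — eye-head gaze shifts; 2 (target presentation) x 2
  (background) x 2 (gaze-shift mode) = 8 conditions x 56 trials;
* experiment 2 — eye-only gaze shifts (head immobile); 4 conditions;
* experiment 3 — background motion with visual velocity gains 1.0/1.15/1.3
  under unrestricted vs sequential gaze shifts = 6 conditions.

One global seed is fanned out deterministically to per-subject and per-trial
substreams, so re-running with the same config is bit-identical. Outputs are
delimited text tables plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eye_events import detect_saccades, fixation_duration, primary_saccade_amplitude
from .inference import AnovaResults, EffectResult, fit_gain_slopes, rm_anova, slopes_vs_zero
from .kinematics import detect_head_movement
from .psychometrics import PsychometricModel
from .synthetic import (
    COMPARISON_POSITIONS,
    GazeShiftScenario,
    HeadMovementSpec,
    ObserverSpec,
    TrialScheduleSpec,
    generate_gaze_trace,
    generate_head_trace,
    generate_trial_schedule,
    simulate_responses,
)
from .io import write_trials

__all__ = ["RunConfig", "RunResult", "experiment_conditions", "run_experiment"]


@dataclass
class RunConfig:
    """Configuration of one simulated experiment run.

    Detection thresholds default to the study's printed values (3 deg/s
    onset/offset criterion, 10-deg minimum head movement, 1-deg saccade-onset
    and 0.1-deg offset differences, 30-ms minimum saccade duration, 10-sample
    smoothing window, +/-1.37-deg stimulus range); every one of them can be
    overridden. The observer-population block sets the generating PHA/JND
    structure (see docs/methods.md for the provenance of the defaults).
    """

    experiment: int = 1
    n_subjects: int = 24
    seed: int = 0
    out_dir: Optional[str] = None

    # detection / analysis constants
    velocity_threshold: float = 3.0
    min_head_amplitude: float = 10.0
    smoothing_window: int = 10
    saccade_onset_diff: float = 1.0
    saccade_offset_diff: float = 0.1
    min_saccade_duration: float = 0.030
    fixation_window: float = 1.0
    stimulus_range: float = 1.37
    slope_tails: str = "one"

    # schedule
    comparison_positions: Sequence[float] = COMPARISON_POSITIONS
    repetitions_per_position: int = 8
    gains: Sequence[float] = (1.0, 1.15, 1.3)

    # trace synthesis
    simulate_traces: bool = True
    write_trace_examples: bool = False
    head_velocity_noise_sd: float = 3.0
    head_position_noise_sd: float = 0.01
    eye_noise_sd: float = 0.1

    # observer population (generating truth)
    pha_grand_mean: float = 0.12
    pha_subject_sd: float = 0.15
    pha_target_effect: float = 0.12   # +stationary / -flashed
    pha_background_effect: float = 0.09  # +grating / -none
    pha_eye_only_shift: float = -0.36
    jnd_log_mean: float = float(np.log(0.8))
    jnd_log_sd: float = 0.15
    jnd_target_ratio: float = 1.12    # flashed JND / stationary JND (applied +/-)
    exp3_pha_mode_mean: dict = field(default_factory=lambda: {
        "unrestricted": 0.08, "sequential": 0.26})
    exp3_pha_gain_slope: dict = field(default_factory=lambda: {
        "unrestricted": 0.5, "sequential": 0.15})

    # movement amplitudes (deg): mean head / saccade per context
    head_amp_stationary: float = 19.16
    head_amp_flashed: float = 18.20
    head_amp_unrestricted3: float = 20.93
    head_amp_sequential3: float = 19.53
    head_amp_sd: float = 1.3
    saccade_amp_stationary: float = 18.58
    saccade_amp_flashed: float = 17.25
    saccade_amp_sd: float = 1.0
    mean_secondary_saccades: float = 1.0  # unrestricted mode, Poisson mean

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparison_positions"] = list(self.comparison_positions)
        d["gains"] = list(self.gains)
        return d


@dataclass
class RunResult:
    """Bundle returned by :func:`run_experiment`."""

    config: RunConfig
    fits: pd.DataFrame
    events: pd.DataFrame
    fixation: pd.DataFrame
    stats: dict[str, AnovaResults]
    slope_tests: dict[str, EffectResult]
    slopes: pd.DataFrame
    manifest: dict


def experiment_conditions(config: RunConfig) -> list[dict]:
    """The condition grid of the configured experiment."""
    if config.experiment == 1:
        grid = itertools.product(("stationary", "flashed"),
                                 ("grating", "none"),
                                 ("unrestricted", "sequential"))
        return [{"target_presentation": t, "background": b, "gaze_mode": m,
                 "gain": 1.0} for t, b, m in grid]
    if config.experiment == 2:
        grid = itertools.product(("stationary", "flashed"),
                                 ("grating", "none"))
        return [{"target_presentation": t, "background": b,
                 "gaze_mode": "eye_only", "gain": 1.0} for t, b in grid]
    grid = itertools.product(("unrestricted", "sequential"), config.gains)
    return [{"target_presentation": "stationary", "background": "grating",
             "gaze_mode": m, "gain": float(g)} for m, g in grid]


def _observer_for(config: RunConfig, cond: dict, base_pha: float,
                  base_jnd: float) -> ObserverSpec:
    """Generating observer for one subject x condition cell."""
    if config.experiment == 3:
        mode = cond["gaze_mode"]
        pha = (base_pha - config.pha_grand_mean
               + config.exp3_pha_mode_mean[mode]
               + config.exp3_pha_gain_slope[mode] * (cond["gain"] - 1.15))
        jnd = base_jnd
    else:
        sign_t = 1.0 if cond["target_presentation"] == "stationary" else -1.0
        sign_b = 1.0 if cond["background"] == "grating" else -1.0
        pha = (base_pha + sign_t * config.pha_target_effect
               + sign_b * config.pha_background_effect)
        if cond["gaze_mode"] == "eye_only":
            pha += config.pha_eye_only_shift
        jnd = base_jnd * config.jnd_target_ratio ** (-sign_t / 2.0)
    return ObserverSpec(pha=pha, jnd=max(jnd, 0.05))


def _head_amplitude_mean(config: RunConfig, cond: dict) -> float:
    if config.experiment == 3:
        return (config.head_amp_unrestricted3
                if cond["gaze_mode"] == "unrestricted"
                else config.head_amp_sequential3)
    return (config.head_amp_stationary
            if cond["target_presentation"] == "stationary"
            else config.head_amp_flashed)


def _simulate_trial_traces(config: RunConfig, cond: dict,
                           rng: np.random.Generator) -> dict:
    """Generate and analyse the head/gaze traces of one trial."""
    scenario = GazeShiftScenario(
        gaze_mode=("sequential" if cond["gaze_mode"] == "sequential"
                   else "unrestricted"),
        target_presentation=cond["target_presentation"],
        background=("grating" if cond["background"] == "grating"
                    else "none"),
        visual_velocity_gain=max(cond["gain"], 1.0),
    )
    eye_head = cond["gaze_mode"] != "eye_only"
    if eye_head:
        amp = float(np.clip(rng.normal(_head_amplitude_mean(config, cond),
                                       config.head_amp_sd), 5.0, 32.0))
    else:
        amp = 0.0
    spec = HeadMovementSpec(
        amplitude=amp,
        velocity_noise_sd=config.head_velocity_noise_sd,
        position_noise_sd=config.head_position_noise_sd,
        direction=1 if eye_head else 0,
    )
    # generous trace length: slowest plausible movement still fits
    v_floor = max(spec.ms_intercept + spec.ms_slope * amp
                  - 5.0 * config.head_velocity_noise_sd, 8.0)
    duration = 0.35 + (2.0 * amp / v_floor if amp > 0 else 0.5) + 0.25
    head = generate_head_trace(spec, duration=duration, onset_time=0.35,
                               seed=int(rng.integers(2 ** 31)))

    sac_mean = (config.saccade_amp_stationary
                if cond["target_presentation"] == "stationary"
                else config.saccade_amp_flashed)
    sac_amp = float(np.clip(rng.normal(sac_mean, config.saccade_amp_sd),
                            5.0, 21.0))
    n_secondary = 0
    if eye_head and scenario.gaze_mode == "unrestricted":
        n_secondary = int(min(rng.poisson(config.mean_secondary_saccades), 3))
    gaze = generate_gaze_trace(
        scenario, head, sac_amp, seed=int(rng.integers(2 ** 31)),
        n_secondary_saccades=n_secondary, noise_sd=config.eye_noise_sd)

    event = detect_head_movement(
        head, threshold=config.velocity_threshold,
        min_amplitude=config.min_head_amplitude,
        window=config.smoothing_window)
    saccades = detect_saccades(
        gaze, onset_threshold=config.saccade_onset_diff,
        offset_threshold=config.saccade_offset_diff,
        min_duration=config.min_saccade_duration)
    fixation = None
    if event.valid:
        fixation = fixation_duration(
            gaze, event, target_position=gaze.meta["landing_position"],
            window=config.fixation_window, saccades=saccades)
    try:
        sac_primary = primary_saccade_amplitude(saccades)
    except ValueError:
        sac_primary = np.nan
    return {"head": head, "gaze": gaze, "event": event,
            "saccades": saccades, "fixation": fixation,
            "saccade_amplitude": sac_primary}


def run_experiment(config: RunConfig) -> RunResult:
    """Run the configured experiment end to end.

    For every subject x condition a balanced 56-trial session is scheduled,
    2AFC responses are drawn from the subject's generating observer, traces
    are synthesized and passed through the detectors (unless
    ``simulate_traces`` is off), a psychometric function is fitted, and the
    experiment's inferential statistics are computed on the per-subject
    summaries. Subjects whose fit fails the inclusion rule in any condition
    are dropped from the inference stage, mirroring the study's
    within-subject exclusion policy.
    """
    conditions = experiment_conditions(config)
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)

    trial_rows: list = []
    fit_rows: list[dict] = []
    event_rows: list[dict] = []
    fixation_rows: list[dict] = []
    trace_examples: list[tuple[str, object, object]] = []

    for si, sseq in enumerate(subj_seqs):
        subject = f"s{si:02d}"
        srng = np.random.default_rng(sseq)
        base_pha = float(srng.normal(config.pha_grand_mean,
                                     config.pha_subject_sd))
        base_jnd = float(np.clip(
            np.exp(srng.normal(config.jnd_log_mean, config.jnd_log_sd)),
            0.3, 2.0))
        for ci, cond in enumerate(conditions):
            crng = np.random.default_rng(np.random.SeedSequence(
                entropy=config.seed, spawn_key=(si, ci)))
            observer = _observer_for(config, cond, base_pha, base_jnd)
            schedule = generate_trial_schedule(
                TrialScheduleSpec(
                    comparison_positions=config.comparison_positions,
                    repetitions_per_position=config.repetitions_per_position,
                    randomize=True, seed=int(crng.integers(2 ** 31))),
                subject=subject, **cond)
            trials = simulate_responses(schedule, observer,
                                        seed=int(crng.integers(2 ** 31)))
            trial_rows.extend(trials)

            cond_label = "_".join(str(cond[k]) for k in
                                  ("gaze_mode", "target_presentation",
                                   "background", "gain"))
            n_excluded = 0
            if config.simulate_traces:
                for ti, _trial in enumerate(trials):
                    sim = _simulate_trial_traces(config, cond, crng)
                    ev = sim["event"]
                    event_rows.append({
                        "subject": subject, "condition": cond_label,
                        "trial": ti, "onset_time": ev.onset_time,
                        "offset_time": ev.offset_time,
                        "peak_velocity": ev.peak_velocity,
                        "peak_time": ev.peak_time,
                        "amplitude": ev.amplitude,
                        "duration_ms": ev.duration, "valid": ev.valid,
                        "exclusion_reason": ev.exclusion_reason,
                        "saccade_amplitude": sim["saccade_amplitude"],
                    })
                    if not ev.valid:
                        n_excluded += 1
                    if sim["fixation"] is not None:
                        fixation_rows.append({
                            "subject": subject, "condition": cond_label,
                            "trial": ti,
                            "fixation_fraction":
                                sim["fixation"].fixation_fraction,
                            "n_saccades_during":
                                sim["fixation"].n_saccades_during,
                            **cond,
                        })
                    if config.write_trace_examples and ti == 0:
                        trace_examples.append(
                            (f"{subject}_{cond_label}", sim["head"],
                             sim["gaze"]))

            fit = PsychometricModel.from_trials(
                pd.DataFrame({
                    "comparison_deg": [t.comparison_deg for t in trials],
                    "response": [t.response for t in trials]})).fit()
            fit_rows.append({
                "subject": subject, **cond,
                "pha": fit.pha, "sigma": fit.sigma, "jnd": fit.jnd,
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
                "included": bool(fit.converged
                                 and abs(fit.pha) <= config.stimulus_range),
                "true_pha": observer.pha, "true_jnd": observer.jnd,
            })

    fits = pd.DataFrame(fit_rows)
    events = pd.DataFrame(event_rows)
    fixation = pd.DataFrame(fixation_rows)

    # within-subject exclusion: a subject failing inclusion anywhere is out
    bad = fits.loc[~fits["included"], "subject"].unique().tolist()
    kept = fits[~fits["subject"].isin(bad)]

    factors = {1: ["target_presentation", "background", "gaze_mode"],
               2: ["target_presentation", "background"],
               3: ["gaze_mode", "gain"]}[config.experiment]

    stats_out: dict[str, AnovaResults] = {}
    slope_tests: dict[str, EffectResult] = {}
    slopes_df = pd.DataFrame()
    if kept["subject"].nunique() >= 2:
        for dv in ("pha", "jnd"):
            stats_out[dv] = rm_anova(kept, dv=dv, within=factors)
        if config.simulate_traces and not fixation.empty:
            fx = (fixation[fixation["subject"].isin(kept["subject"])]
                  .groupby(["subject"] + factors, as_index=False)
                  ["fixation_fraction"].mean())
            complete = (fx.groupby("subject").size()
                        == fx.groupby("subject").size().max())
            fx = fx[fx["subject"].isin(complete[complete].index)]
            if fx["subject"].nunique() >= 2 and config.experiment != 2:
                stats_out["fixation_fraction"] = rm_anova(
                    fx, dv="fixation_fraction", within=factors)
        if config.experiment == 3:
            slope_rows = []
            for mode in ("unrestricted", "sequential"):
                sub = kept[kept["gaze_mode"] == mode]
                sf = fit_gain_slopes(sub, gain_col="gain", pha_col="pha")
                slope_rows.extend({"gaze_mode": mode, "subject": s.subject,
                                   "slope": s.slope,
                                   "intercept": s.intercept} for s in sf)
                slope_tests[mode] = slopes_vs_zero(
                    sf, tails=config.slope_tails,
                    name=f"{mode} slopes vs 0")
            slopes_df = pd.DataFrame(slope_rows)

    excluded_fraction = (float((~events["valid"]).mean())
                         if not events.empty else 0.0)
    manifest = {
        "software": {"package": "gazeshift", "version": __version__},
        "config": config.to_dict(),
        "n_conditions": len(conditions),
        "conditions": conditions,
        "n_fits": len(fits),
        "n_trials": len(trial_rows),
        "excluded_subjects": bad,
        "excluded_trial_fraction": excluded_fraction,
        "stats": {
            name: res.as_dataframe().to_dict(orient="records")
            for name, res in stats_out.items()},
        "slope_tests": {
            name: {"t": r.t, "df": r.df_num, "p": r.p}
            for name, r in slope_tests.items()},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(out / "trials.csv", trial_rows)
        fits.to_csv(out / "fits.csv", index=False)
        if not events.empty:
            events.to_csv(out / "head_events.csv", index=False)
        if not fixation.empty:
            fixation.to_csv(out / "fixation.csv", index=False)
        for name, res in stats_out.items():
            res.as_dataframe().to_csv(out / f"stats_{name}.csv", index=False)
        if not slopes_df.empty:
            slopes_df.to_csv(out / "slopes.csv", index=False)
        if trace_examples:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            from .io import write_traces
            for label, head, gaze in trace_examples:
                write_traces(tdir / f"{label}.csv", [head, gaze])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(config=config, fits=fits, events=events,
                     fixation=fixation, stats=stats_out,
                     slope_tests=slope_tests, slopes=slopes_df,
                     manifest=manifest)
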