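# Methods

This note documents the models, conventions and numerical choices behind
`gazeshift`, and what the synthetic-data studies do and do not establish.

## Synthetic head movements

A head movement of amplitude A (deg) follows a **raised-cosine velocity
profile**: v(t) = v_peak/2 · (1 − cos 2πt/D) on t ∈ [0, D], which starts and
ends at exactly zero velocity (compatible with a 3 deg/s onset/offset
criterion), is C¹-smooth, and integrates exactly to A, giving
D = 2A / v_peak. Peak velocity is drawn from the **main sequence**

    v_peak = 13.22 + 1.27 · A  (+ Gaussian scatter, SD `velocity_noise_sd`)

with amplitude in degrees and velocity in deg/s. The orientation of this
line (peak velocity as a function of amplitude, not the converse) is
self-consistent: evaluated at the mean amplitude of 18.83° it predicts
37.13 deg/s against a mean peak velocity of 37.01 deg/s (0.33%); the
converse reading is dimensionally inconsistent with those means. The
default trace rate is 913.68 Hz (head) and 120 Hz (gaze); both are
configurable, and all kinematics use actual timestamps, so recorder jitter
is handled.

**Tracker noise.** Head-position noise defaults to 0.01° RMS, low-pass
filtered over 100 ms. White noise at 913.68 Hz of any appreciable RMS is
not a realistic model of an HMD tracker and would dominate first-difference
velocities (0.05° white noise implies ~65 deg/s sample-to-sample velocity
noise, ~6.5 deg/s after 10-sample averaging — enough to swamp a 3 deg/s
criterion); slowly varying jitter of ~0.01° matches SteamVR-class tracking.
Eye noise defaults to 0.1° RMS white at 120 Hz, which is compatible with
the 1° saccade-onset criterion (consecutive-sample noise SD ≈ 0.14°).

**Gaze synthesis.** The eye makes a 25-ms primary saccade toward the target
ending 100 ms before the head starts, then holds gaze on its landing
position throughout the head rotation (idealized vestibulo-ocular reflex).
In unrestricted mode, k secondary saccades are injected during the head
movement as a one-sample step of 2° followed by a < 0.1°/sample glide back;
this shape registers as exactly one event under the amplitude-difference
detection rules (a step-out/step-back pair would register as two) while
lowering the fixation fraction. Sequential mode injects none, so its
synthetic fixation fraction is ~100%, higher than the ~90% typical of real
compliance; the generator idealizes instruction-following.

## Event detection

**Head movements.** Velocity is the time-based first difference; smoothing
is a forward ("consecutively following") moving average over 10 samples,
with a shrinking window at the tail — zero-padding would fabricate spurious
subthreshold samples and hence phantom onsets. The 3 deg/s criterion is
applied to the smoothed series: the peak is the global argmax of |v|, onset
the last below-threshold sample before it, offset the first after it.
Movements that never exceed 3 deg/s or whose onset-to-offset amplitude is
below 10° (half the fixation-to-target distance) are invalid with exactly
one exclusion reason; degenerate traces never raise. When a trace contains
several suprathreshold lobes, the event around the global peak is returned
and the extra lobes are counted on the event (`extra_lobes`) — a single
movement per trial is the design assumption. Because onset/offset sit where
the speed crosses 3 deg/s, the detected amplitude under-reports the
generated one by at most the displacement accumulated below threshold
(≈ 0.1° for a raised cosine), and the smoothed peak under-reports the true
peak by the curvature of the profile across the 10-sample window (< 0.1%
at 913 Hz) — both negligible against the 3 deg/s generating scatter used in
the recovery studies.

**Saccades.** At 120 Hz velocity thresholds are unreliable, so detection
uses amplitude changes between consecutive samples irrespective of elapsed
time: onset is the sample immediately preceding the first difference ≥ 1°
(single-sample comparison, no multi-sample accumulation); offset is the
earliest sample at least 30 ms after onset that deviates < 0.1° from its
predecessor; scanning resumes at each offset, making events non-overlapping
and ordered. If the offset criterion is never met the event closes at the
trace end and is flagged truncated. Detection runs on gaze-in-world, so VOR
counter-rotation does not trigger detections.

**Fixation fraction.** The share of the head-movement interval in which
gaze is within 1.0° of the target (the trial-control fixation window) and
no saccade is in progress, with dwell times taken from inter-sample
intervals clipped to the head-movement window. The pipeline evaluates it
against the primary saccade's landing position, so the metric isolates eye
stability during the head movement from saccadic undershoot.

## Psychometrics

Per condition, responses are pooled across sessions into binomial counts
per comparison position and fitted by maximum likelihood with
P(right; x) = Φ((x − μ)/σ) — likelihood on counts, not least squares on
proportions, and no lapse term by default (the generator supports a lapse
rate for robustness studies). Optimization is L-BFGS-B in (μ, log σ) from
five deterministic multistarts (data-driven 50%-crossing starts keep the
optimum equivariant under translation and reflection of the stimulus axis);
ties are broken by highest log-likelihood, then smallest σ; a start that
stalls in the line search exactly at the optimum is superseded by a cleanly
converged start at the same likelihood. All-left or all-right data leave μ
unidentified and return an unconverged fit rather than raising.

Conventions:

* **JND = σ** (the 50%→84.1% half-width). The constant is isolated in
  `JND_SCALE`, so the 75%-point convention (0.6745·σ) is a one-line change.
* **Inclusion**: a fit is included iff it converged and |PHA| ≤ 1.37°, the
  half-range of the presented comparisons; the pipeline drops a subject
  entirely if any condition fails this, matching a within-subject design.

At the study's sampling (7 positions × 64 trials), simulate-and-refit
replicates put the estimator's bias below 0.03° in μ and 0.08° in σ
(`gazeshift.recovery.psychometric_recovery`).

## Inference

The repeated-measures ANOVA implements the classical balanced
within-subject decomposition: each effect is tested against its interaction
with subjects, with SS computed by inclusion–exclusion over marginal means.
Greenhouse–Geisser ε is computed from the sample covariance of the
subject-level scores projected onto orthonormal effect contrasts
(Kronecker products across the factors of an interaction),
ε = tr(M)²/(d·tr M²), clipped to [1/d, 1]; it equals 1 for 2-level effects
and is applied to both degrees of freedom whenever d > 1 (for
compound-symmetric covariance it is 1 and the correction is a no-op).
Partial η² = SS_eff/(SS_eff + SS_err). **Observed power** follows the
convention of mainstream GUI statistics packages — noncentrality
λ = F·df_num against the central-F critical value at α = 0.05 on the
ε-scaled dfs — and is approximate by construction. Zero error variance
yields F = ∞, p = 0 and a degenerate flag instead of an exception. The
implementation is cross-checked in the test suite against pingouin
(1-factor GG) and statsmodels AnovaRM (3-factor F/df), and against
longhand and contrast-projection oracles to 1e−10.

Post hoc comparisons are two-tailed paired t-tests with explicit Bonferroni
correction (p·m capped at 1; m passed by the caller). Gain slopes are
per-subject OLS lines through exactly three (gain, PHA) points; the test of
slopes against zero is **one-tailed (positive) by default** — the directed
hypothesis that stronger background motion shifts localization further —
with a two-tailed flag. P-values are kept at full precision.

## Pipeline defaults

The simulated observer population uses the group-level means of the
paradigm as generating values: condition effects of ±0.12° (target
presentation) and ±0.09° (grating presence) around a 0.12° grand-mean PHA,
an eye-only shift of −0.36°, JND ratio 1.12 between flashed and stationary
targets around a log-normal subject JND centred at 0.8°, head-movement
amplitude means of 19.16°/18.20° (stationary/flashed) and 20.93°/19.53°
(unrestricted/sequential with background motion), saccade amplitudes of
18.58°/17.25°, and PHA-on-gain slopes of 0.5 (unrestricted) and 0.15
(sequential) deg per unit gain. These are simulation conditions, not
reproduction targets: group-level empirical statistics depend on real
participant data and are out of scope.

Seeding fans one global seed out via `SeedSequence` spawn keys to
per-subject and per-condition substreams; identical configurations produce
bit-identical output files. Stage logs record exclusion counts;
excluded-trial fractions are data-dependent summaries, not targets.

## Problem sizes

The recovery studies use 500 traces (main sequence), 200 replicates
(psychometric bias), 1000 traces (detector oracle equivalence) and 1000
replicates (ANOVA null size, n = 24); end-to-end pipeline checks run 3–10
subjects. These sizes put simulation standard errors well below the effect
sizes being verified while keeping the default test run fast.

## Known limitations

* Yaw only; no torsional or translational head motion, no vertical eye
  movements, no binocular geometry.
* No optokinetic-nystagmus dynamics; the moving-background conditions alter
  only the generating PHA, not the eye-movement synthesis.
* The fitted psychometric model has no lapse parameter; heavy lapsing in
  synthetic data will bias σ upward.
* Passing recovery tests on synthetic traces shows the chain is
  self-consistent at realistic noise levels; it does not certify behaviour
  on real recordings with blinks, tracking loss, or non-stationary noise,
  for which no ingestion adapters are provided.
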