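# Methods

This note documents the models, parameters, and design choices behind
vestkit, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic experiments do and do not show.

## Setting

Patients with unilateral or bilateral vestibular hypofunction are prescribed
gaze-stabilization (VOR X1) and balance exercises. In the gamified setting
this toolkit models, an inertial measurement unit (IMU) on the forehead
(VOR) or at the waist (weight shift, single-leg stance) drives a game
character, and the app detects performance mistakes in real time and cues
corrections. The toolkit reproduces the computational pipeline headlessly:
signal in, metrics / error events / game score out, plus the paired
statistics used to compare exercising with and without the app.

## Session data model

A trial is an `AngleSeries`: timestamps (s since trial start) and roll,
pitch, yaw in degrees, at a nominal sampling rate (default 50 Hz — a rate
typical of consumer IMUs; the source system's actual rate is not published),
in a `head` or `pelvis` frame, referenced either `absolute` or
`neutral-relative`. Pelvis convention: roll = mediolateral (ML) lean,
pitch = anteroposterior (AP) lean. On disk a session is a JSON envelope
(subject, condition, prescription, results) plus a side-car CSV
(`t,roll_deg,pitch_deg,yaw_deg`); everything is degrees and seconds, and a
write→read round trip is bit-exact.

Prescription defaults: VOR 20° from midline at 1 Hz for 60 s per plane;
weight shift 120 s per direction; single-leg stance 45 s per leg. The
weight-shift amplitude and pace are not published; the defaults (10°,
0.25 Hz — a slow deliberate lean) were chosen once as clinically plausible
and are configurable.

## Synthetic signal generator

The generator emulates the *statistical structure* of exercise performance,
not vestibular physiology. One trial is

    x(t) = A_k · w(φ(t)) + drift·t + ε(t),   φ̇ = 2π f_k,

where `w` is a sinusoid (or triangle, for near-constant-velocity sweeps),
and the half-cycle index k carries the human variability: per-half-cycle
amplitude A_k = A(1 + a·z_k) and frequency f_k = f(1 + b·z'_k) with
independent standard-normal z clipped at ±2. Defaults: amplitude jitter
a = 5 %, frequency jitter b = 3 %, white Gaussian sensor noise
SD 0.5°, linear drift 0.5°/min. The clipping encodes bounded
trial-to-trial variability; it also guarantees that a clean (error-free)
signal cannot wander past the error-detector thresholds, which an unbounded
tail would do with positive probability.

Each trial starts with a hold-still calibration segment (default 2 s,
inside the prescribed duration) at the configured neutral orientation; when
the hold is zero and the neutral is zero the series is emitted already
neutral-relative. Single-leg stance, where the prescription is stillness,
is modelled as band-limited (0.5 Hz) Gaussian wander of ML and AP with
configurable RMS tilt (default 1.5°).

Labeled error episodes can be injected: `too_far` scales the amplitude
envelope so extrema reach A + magnitude; `too_fast` multiplies the local
phase advance; `jerky` superimposes short Gaussian transients (width
0.05 s, ~1 per second, alternating sign); `chin_motion` adds off-plane
oscillation of the given peak-to-peak. Ground-truth intervals ride along in
a truth list.

What the generator does **not** model: vestibular plant dynamics, fatigue
or learning trends within a trial, correlated (pink) sensor noise, and the
real error classifiers' feature space. Passing tests therefore demonstrate
correctness of the pipeline's mechanics and calibration of its statistics
under this noise model — not clinical performance on patient recordings.

## Kinematic pipeline

1. **Calibration** — per-channel mean over the first 2 s; the calibration
   is rejected if any channel's SD over the window exceeds a stillness
   tolerance (default 1°; conditions with sensor noise near 1° SD need the
   tolerance raised above the noise floor, since a perfectly still hold
   already reads SD ≈ noise SD).
2. **Re-referencing** — subtract the neutral pose; constant offsets in the
   absolute angles therefore never affect any metric.
3. **Filtering** — zero-phase 4th-order Butterworth low-pass (order 2
   forward + backward). The default cutoff adapts to the prescription,
   4·f clamped to [2, 6] Hz: the oscillation needs only a few harmonics of
   bandwidth, and a tighter cutoff suppresses the noise maxima that
   otherwise bias detected peak values upward (with a fixed 6 Hz cutoff and
   1° noise the ROM of a 10° trial reads up to ~5 % high; adaptive, ≤ ~2 %).
   An explicit cutoff can be configured.
4. **Peak finding** — maxima and minima found separately (prominence 5°,
   same-sign separation 0.25/f s), merged, with alternation enforced by
   keeping the larger-magnitude of adjacent same-sign candidates.
5. **Cycle metrics** — ROM per excursion between alternating extrema
   (prescribed 20° from midline ⇒ expected ROM 40° peak-to-peak; the
   midline-to-peak convention is obtained by halving); frequency per full
   cycle between same-sign extrema. Variances are sample variances
   (ddof = 1). At least 3 extrema are required.
6. **Balance metrics** — resultant angle √(ML² + AP²); its mean peak
   excursion (prominence 0.5°) summarizes overall pelvic excursion;
   smoothness is scored as fluency.

**Fluency** = 1 / dimensionless jerk, with dimensionless jerk
∫ j² dt · T⁵ / pp², j the third derivative, pp the peak-to-peak
amplitude. It is amplitude-scale invariant and strictly decreases as jerk
transients are added. The third derivative uses 4th-order finite
differences *including one-sided boundary stencils*: with ordinary
second-order edge handling the boundary errors, cubed through three
differentiations, contribute ~0.5 % to the squared-jerk integral of a pure
sinusoid; with the 4th-order stencils the error is ~0.002 %. The measure is
isolated behind `compute_fluency` so an alternative smoothness metric
(e.g. spectral arc length) can be swapped in. Fluency is undefined (flagged
`None`) for a motionless trial.

## Error detection

Detection runs on VOR trials, per contiguous 7 s window over the trial. A
60 s trial yields 8 windows: a terminal remainder shorter than 2/3 of a
window is merged into the previous one, so the last window spans 49–60 s;
a remainder of at least 2/3 window stands alone; a series shorter than half
a window is rejected.

Per window, with thresholds expressed relative to the prescription so they
generalize beyond 20°/1 Hz:

| error | statistic (on the filtered window) | default threshold |
|---|---|---|
| `too_far` | max absolute primary-channel excursion | 1.25 · A |
| `too_fast` | mean per-cycle frequency from window extrema | 1.25 · f |
| `jerky` | dimensionless jerk ÷ ideal-sinusoid value (2πf)⁶T⁶/8 | 3.0 |
| `chin_motion` | off-plane channel peak-to-peak | 10° |

The general statistics use a 6 Hz low-pass; the jerk statistic uses a
dedicated 4 Hz low-pass, because broadband noise passed at 6 Hz dominates a
third derivative (on clean default-noise trials the window jerk ratio stays
below ~1.5; the threshold 3.0 doubles that, while injected bursts reach
6× and more). Severity is statistic/threshold − 1. At most one event per
type per window; detection is deterministic. Each error type maps to a
fixed feedback cue delivered as auditory + written (the exact wording is a
toolkit convention; none is published).

**Correction ledger.** Per trial and error type: *made* = any flagged
window; *corrected* = the last flagged window is followed by at least two
clean windows at the end of the trial (index ≤ n − 3); otherwise *made but
not corrected* — an operationalization chosen here, since no formal
definition is published. By construction corrected + not-corrected = made,
per trial, per type, and in every cohort aggregate.

The original app detected these errors with trained classifiers that are
not public; the rule-based detectors preserve the observable behaviour
(taxonomy, 7 s cadence, feedback, ledger) with transparent thresholds.

## Game engines

All engines are pure functions of the series and a config; the only
randomness (omnidirectional coin order) is seeded. Score geometry is a
toolkit convention, configurable, since the app's is unpublished.

* **Daring Escape** (VOR): obstacles spawn one per half-cycle — at 2f per
  second, alternating cued sides — over the trial; rate f comes from the
  prescription directly or from an angular velocity via f = v/(4A) (a
  constant-speed sweep covers 4A per cycle; if both are given they must
  agree to 1 %). An obstacle is avoided iff the primary angle crosses the
  avoid threshold (default A/2) on the cued side before the half-cycle
  deadline. The noiseless prescribed trajectory scores 120/120.
* **Treasure Hunter** (weight shift): character position = 10 screen
  units/deg × (ML, AP). Coins spawn sequentially at 80 % of the prescribed
  on-screen excursion (laterally for ws_ml, sagittally for ws_ap, eight
  compass points in seeded order for ws_omni), are picked up by dwelling
  within the coin radius (25 % of the prescribed excursion) for 0.5 s, and
  banked by returning within that radius of the origin. Opportunities =
  prescribed cycles in the trial (30 at 0.25 Hz × 120 s).
* **Balancing Act** (single-leg): per 1 s interval the mean resultant tilt
  earns 2 coins below 2°, 1 coin in [2°, 5°), 0 at or above 5°; a level
  pelvis over 45 s earns exactly 90 coins.

Trophies: gold ≥ 90 %, silver ≥ 75 %, bronze ≥ 50 % of the maximum
attainable coins; boundaries take the higher tier.

## Statistics

Paired differences (app − no-app), one per subject, are screened with the
omnibus skew+kurtosis normality test (K² = Z(skew)² + Z(kurtosis)²,
χ² with 2 df; results for n < 20 are flagged as unreliable, zero-variance
samples are an error). Normal differences take the paired t-test; the rest
take the Wilcoxon signed-rank test with zero differences dropped and
average ranks for ties. α = 0.05, no multiple-comparison correction (an
optional Holm adjustment exists but is off by default). The cohort
comparison produces one row per exercise × metric — ROM mean/variance and
frequency mean/variance for VOR and single-axis weight shift; resultant
excursion and fluency for balance tasks — excluding (with a warning)
subjects missing a condition. Note the routing decision itself consumes the
5 % level; empirical size of the full procedure stays within 0.05 ± 0.02 at
n = 40 in the calibration runs.

The omnidirectional weight-shift exercise has no single oscillation axis,
so it is summarized with the balance metrics rather than per-axis cycle
metrics; the single-axis games carry the ROM/frequency comparisons.

## Problem sizes in tests and the acceptance script

Parameter recovery: A ∈ {10, 20, 30}° × f ∈ {0.5, 1, 2} Hz × 20 seeds at
noise SD 1°. Detector confusion: 100 injected + 100 clean 60 s trials, with
the injection schedule aligned to windows 1/3/5/6 and magnitudes ≥ 1.5× the
corresponding thresholds (overshoot to 38° vs 25; ×2 speed vs 1.25 Hz;
bursts reaching ≥ 6× the jerk ratio vs 3; 15° pk-pk vs 10). Ledger: a
10-subject cohort with 4 corrected / 2 uncorrected overshooters. Statistics:
2000 null replicates and 200 power replicates at n = 40; routing on 50
normal/lognormal pairs. Cohort finding: 20 cohorts of 40 subjects with the
no-app pacing jitter inflated 4×. These sizes give stable Monte-Carlo
estimates at the tolerances quoted while keeping the full run fast.

## Known limitations

* The synthetic noise model (white noise, linear drift, independent
  clipped-Gaussian cycle jitter) is a stand-in; real subjects' noise
  spectra are uncharacterized in any public source.
* The error detectors are threshold rules, not the original trained
  classifiers; agreement with the original system's per-window labels
  cannot be verified.
* Game geometry (obstacle collision, coin distances, tilt bands, trophy
  cutoffs) is a documented convention, not a reconstruction.
* The pipeline consumes orientation angles; sensor fusion from raw
  accelerometer/gyroscope data is out of scope, as are questionnaires and
  any UI/hardware concerns.
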