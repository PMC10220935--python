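# Methods

This note records the modelling conventions, the open design choices and
why they were resolved the way they were, what the synthetic generators
do and do not emulate, and the problem sizes the tests use.

## Signal conditioning

The device samples three axes at 32 Hz with 3 mG resolution and strips
gravity with a 0.7 Hz high-pass filter before averaging absolute
accelerations over 10-s epochs. Three conventions are undocumented for
the device and are fixed here (all configurable):

**Filter realization.** A 4th-order Butterworth high-pass applied
forward–backward (`scipy.signal.sosfiltfilt`). Only the cutoff is
documented; zero-phase filtering avoids phase lag smearing epoch
boundaries, at the cost of a non-causal response the physical device
cannot have. The forward–backward pass squares the magnitude response
(≈ −67 dB at 0.1 Hz, < 0.1 % ripple at 2 Hz), which the frequency-response
tests pin down.

**Synthesis.** The "synthesized" epoch acceleration is the Euclidean norm
of the three per-axis mean absolute values — the standard vector-magnitude
convention for this device family.

**Gravity in the unfiltered value.** ACunfil removes the per-epoch,
per-axis mean before taking absolute values. Without this the static
~1000 mG gravity vector dominates ACunfil and the 1.16 ratio threshold
could never trigger; per-epoch DC removal keeps exactly the 0–0.7 Hz band
content the ratio is designed to detect while discarding the static
component. This treats an epoch (10 s) as long relative to postural
change.

Trailing partial epochs are dropped, never padded.

## Classification and METs

The classifier is the three printed conditionals (sedentary below
29.9 mG ACfil; otherwise non-locomotive at ratio ≥ 1.16, else
locomotive). Two boundary conventions:

* ACfil exactly 29.9 mG is unassigned by the printed rules ("< 29.9" and
  "> 29.9"); it is assigned to sedentary. At that point the sedentary and
  non-locomotive MET equations differ by 0.0022 METs, so either choice is
  numerically immaterial; the tests assert the < 0.01 MET continuity.
* ACfil = 0 makes the ratio undefined; such epochs are sedentary via the
  first branch and the ratio is never evaluated.

Intensity categories use the continuous MET scale: sedentary ≤ 1.5,
light in (1.5, 3.0), MVPA ≥ 3.0. The conventional "1.6–2.9" labelling of
light activity is read as the discrete description of the open interval.
(The device literature also contains a stray "≤ 0.5 METs" sedentary
bound; 1.5 METs is the standard sedentary-behaviour definition and is
used here.)

## Wear filtering

"Zero counts" is interpreted at the epoch level: an epoch is zero when
both synthesized accelerations are below half the 3 mG resolution, and a
minute is zero when all six epochs are. The half-resolution tolerance
matters in practice: zero-phase filter transients bleed ~1 mG into the
first epoch of a genuinely idle period and would otherwise shorten every
zero run by one epoch. Runs of ≥ 60 consecutive zero minutes are
non-wear. Runs are evaluated within calendar days by default
(`WearRules.span_midnight` enables midnight-spanning runs); whether the
original processing macro breaks runs at midnight is unknown, so the
convention is explicit and configurable. Minute METs are the arithmetic
mean of the six constituent epochs (the aggregation rule is not
documented); partial trailing minutes are dropped.

Imputed non-wear minutes (0.9 METs) count toward energy — they represent
assumed resting expenditure — but not toward the intensity-minute
tallies, which describe observed behaviour only.

## Energy model

The AEE convention is `(MET − 1) × RMR_per_min` with RMR = 1.1 × predicted
BMR. The source sentence ("METs multiplied by the estimated resting
metabolic rate") is ambiguous; the raw-MET reading double-counts basal
expenditure and back-calculates to an impossible 24-h MET average when
checked against published TEE magnitudes, while the (MET − 1) form is the
convention of this device's validation literature and reproduces them.
The literal variant is retained (`daily_aee(..., subtract_rest=False)`)
for sensitivity analysis. Negative minute contributions (METs < 1,
including imputed 0.9) are retained.

AEE, TEE and PAL are computed per valid day and averaged across valid
days with equal weights (whether the original analysis used a 14-day
total or a mean of daily values is unstated; equal-weight day averaging
is adopted).

The Nagayoshi adjustment is applied to wear-minute METs only; imputed
non-wear minutes keep 0.9 METs, since the imputation encodes an
assumption rather than a device reading to be recalibrated. Consistency
check the test suite does not own: with this convention a study-scale
schedule maps a predicted PAL of ~1.7 to a Nagayoshi PAL of ~2.05,
matching the magnitude of the published overestimate; adjusting the
imputed minutes as well would push it to ~2.19.

Corrected TEE can be formed against either the predicted or the measured
BMR; both are reported by the validation stage.

## Validation statistics

Errors are predicted − measured; sample SDs use n − 1 (the reporting
convention is unstated; n − 1 is standard). Correction equations are
fitted per sex by OLS of measured on predicted PAL, never pooled. The
fitted residuals have exactly zero mean on the fitting sample (an OLS
identity); the residual SD is the reported prediction-error SD.
Measured-vs-predicted comparisons use paired t tests (the natural design
for within-participant comparisons; pairing is not stated in the source
and is flagged here), sex comparisons unpaired; both two-tailed at
α = 0.05. A fitted slope ≤ 0 (possible in degenerate or tiny samples)
raises an estimation error rather than returning an unusable model.

## Synthetic signal generator

Segments are minimal designs that land robustly on the intended side of
each threshold, not biomechanically realistic gait:

* locomotive: sinusoid at the gait fundamental (default 2 Hz, amplitude
  200 mG) on the vertical axis + 5 mG white noise on all axes. Measured
  epoch ratio ≈ 0.99–1.01 against the 1.16 threshold; ACfil ≈ 127 mG.
* non-locomotive: amplitude split (default 50/50) between the fundamental
  and a 0.2 Hz component. The slow component survives only in ACunfil;
  measured ratio ≈ 1.26–1.29.
* sedentary: 5 mG white noise; ACfil ≈ 7 mG against the 29.9 mG threshold.
* non-wear: exact zeros (still zero after 3 mG quantization).

With these margins every complete in-segment epoch classifies as
scheduled (the epoch engine plus classifier act as the oracle in the
tests). The generator does not emulate step counts, posture transitions,
device orientation error, or the spectral richness of real human
movement — passing tests certify the processing chain's arithmetic and
thresholds, not field validity of the classifier.

## Synthetic cohort generator

Anthropometry is drawn per sex from the cohort-table normal
distributions, truncated at ±3 SD (and clipped to physical ranges) to
avoid nonphysical covariates. Each participant receives a daily schedule:
an overnight non-wear block (Normal(480, 45) min, clipped to [300, 700] —
device removed for sleep), and wear minutes drawn i.i.d. from a
sedentary/light/MVPA mixture. Mixture weights shift with a
per-participant activity trait (MVPA fraction 0.06 + 0.03·trait, light
fraction 0.35 + 0.08·trait, trait ~ N(0,1)) plus a small day-to-day
wobble; category METs are uniform on [0.9, 1.5], [1.6, 2.9] and
[3.0, 6.0]. These defaults were set so the monitor-predicted PAL lands at
≈ 1.70 with between-participant SD ≈ 0.15, matching the validation
cohort's predicted-PAL distribution (1.71 ± 0.13 in women); they are not
an estimate of any real population's schedule. Default recording length
is 7 days (valid days of a two-week protocol).

Ground truth: measured PAL = true_slope × predicted PAL + true_intercept
+ Normal(0, resid_sd) (defaults 0.949 / 0.205 / 0.20, floored at 1.05
since lower PALs are nonphysical); measured BMR = Ganpule prediction ×
(1 + Normal(0, CV)) with CV = 7 %, a typical indirect-calorimetry
repeatability; measured TEE = measured PAL × measured BMR, so the
PAL = TEE/BMR identity holds exactly. Because predicted PAL is computed
through the actual energy model, refitting the correction on a noiseless
cohort recovers the truth to machine precision, and OLS on noisy cohorts
is unbiased — the recovery driver (`analysis/04_correction_recovery.py`)
reports the sampling distribution (per-replicate slope SD ≈ 0.22 at
n = 47, so means over 200 replicates carry a Monte-Carlo SE of ≈ 0.016).

All randomness (anthropometry, schedules, noise) derives from one
top-level seed via a single `numpy` generator, so identical spec + seed
reproduce cohorts and signals bit-for-bit.

## Problem sizes

The test suite and drivers use a scripted 24-h signal (2.8 M samples) for
the end-to-end signal checks, cohorts of 47–69 participants × 7 days for
pipeline checks, 200 replicated cohorts for parameter recovery, and 1000
simulations for t-test calibration; the full suite runs in well under a
minute on one core.

## Known limitations

* The filter realization, synthesis rule, ACunfil gravity handling and
  minute-aggregation rule are declared conventions, not device firmware
  facts; all are parameterized for sensitivity analysis.
* The generator's schedules are stand-ins; agreement on synthetic data
  does not validate the classifier or the correction equations on real
  older-adult data, and the published correction equations apply only to
  populations comparable to the original cohort.
* No step-count algorithm, sleep detection, or alternative non-wear
  rules (e.g. Choi/Troiano) are implemented.
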