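# Methods

## Problem setting

A person's walking gait and heart rate change with mood. Given wrist-worn
motion data (triaxial accelerometer and gyroscope at ~24 Hz) and a chest-strap
heart-rate series recorded while a person walks in a known emotional state
(happy, sad, or neutral, induced by movie or music stimuli), the task is to
recognise the emotional state from one-second windows of the signals. The
central statistical questions are not only *whether* a classifier can do this,
but *what the right evaluation is*: personal (within-user) models vs. models
that transfer across users, and random cross-validation vs. leakage-aware
schemes that respect the temporal structure of the data.

No raw recordings from the original experiment are publicly available, so the
package pairs the analysis pipeline with a first-class synthetic cohort
generator that reproduces the statistical structure the analysis depends on.
All conclusions drawn from the tests are therefore statements about the
pipeline's behaviour on data *with that assumed structure*, not about human
gait itself; the generator's assumptions are spelled out below.

## Pipeline

1. **Preprocessing** (`gaitmood.preprocessing`). Accelerometer channels are
   smoothed with a centred moving-average filter of width 3 samples (edges use
   truncated windows; the gyroscope passes through unfiltered). Recordings are
   cut to the annotated walking interval on half-open `[start, stop)` time
   ranges and re-zeroed.
2. **Windowing and features** (`gaitmood.features`). Walks are segmented into
   24-sample (one-second) windows with 50% overlap; trailing partial windows
   are discarded, so a walk of *n* samples yields `floor((n-24)/12)+1`
   windows. Each window becomes one labeled sample with 107 features:
   17 time-domain statistics per axis for the 6 motion axes (102), the angle
   between the window-mean acceleration vector and each axis (3), the SD of
   the per-sample acceleration magnitude (1), and the aligned heart rate (1).
   Statistic conventions (pinned by golden-value and brute-force-oracle
   tests): sample SD (n−1); energy = mean of squares; population-moment
   skewness and excess kurtosis, defined as 0 on windows whose variance is
   numerically zero relative to their power; linear-interpolation quartiles;
   unscaled median absolute deviation about the median. The heart-rate
   feature is the mean of the 1 Hz samples inside the window's time span,
   falling back to the nearest sample. Sensor subsets (`acc` = 55 columns,
   `acc+hr` = 56, `acc+gyro+hr` = 107) drop excluded columns but keep the
   canonical order `acc_{x,y,z}×stats, gyro_{x,y,z}×stats, angle_{x,y,z},
   mag_sd, heart_rate`.
3. **Models** (`gaitmood.evaluation`). Three classifiers: a majority-class
   baseline (ties break to the lexicographically smallest label; its
   predicted "probabilities" are the constant training class frequencies, so
   its ROC-AUC is 0.5 by construction); L2-regularised logistic regression
   (inverse strength C = 1, features standardised with training-fold
   statistics only); and a 100-tree random forest with library-default
   settings, seeded.
4. **Evaluation schemes.**
   - *Repeated stratified k-fold* (default 10×10) on a single user's windows
     — the conventional personal-model evaluation. It is optimistic whenever
     adjacent windows are correlated, because 50%-overlapping neighbours of a
     test window sit in the training fold (*neighborhood bias*).
   - *Emotion-block CV* (binary labels): each class's windows, in time order,
     are split into 5 contiguous blocks; each of the 10 folds holds out one
     single-class block and trains on the rest. A model can only score well
     here by recognising the emotion rather than the walking period. The
     baseline is re-fit per fold, so removing a whole block flips the
     training majority against the held-out class and baseline accuracy
     collapses to ≈0. Because test folds are single-class, the reported F1 is
     the F1 of the held-out class and ROC-AUC is omitted.
   - *Leave-one-user-out*: train on all other users pooled, test on the
     held-out user.
5. **User lift and inference.** A user lift is the personal model's mean
   accuracy minus the personal baseline's mean accuracy under the same
   scheme. Whether lifts have positive mean across users is tested with a
   one-sided sign-flip permutation test of H₀: mean = 0. The test enumerates
   all 2ⁿ sign patterns exactly whenever 2ⁿ ≤ `n_perm` (default 100 000, so
   exact up to 16 users); otherwise it Monte-Carlo samples with the add-one
   correction `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`. Ties count toward
   the alternative, so the test is conservative and p is never 0. Its
   empirical type-I error at α = 0.05 over 2000 null replicates of 14 users
   is verified to lie in [0.03, 0.07].
6. **Interpretability.** Per user, random-forest feature importances are
   averaged over CV folds and divided by their maximum, so 1.0 marks that
   user's most informative feature; the cross-user distribution is summarised
   per feature by median and quartiles.

## The synthetic cohort generator

`gaitmood.synthetic_data` generates seeded cohorts with the session structure
of a mixed design: each participant walks once per emotion (neutral always
between happy and sad, as a washout), with order counterbalanced by
participant parity, under one of three conditions. Defaults give ~202 s walks
at 24 Hz with ±10 s jitter, i.e. ≈403 one-second windows per emotion per
participant with a realistic between-walk spread.

**Signal model.** Each motion axis is a sum of the first three harmonics of
the step frequency (cadence, population mean 1.8 Hz), plus white noise
(SD 1.2 m/s² for the accelerometer, scaled ×25 for the gyroscope in deg/s)
and a slow random-walk drift (SD 0.01 per sample) that induces within-walk
autocorrelation. Heart rate is a 1 Hz AR(1) series (φ = 0.9, innovation-level
SD 8 bpm) around the participant's emotional set point plus a per-walk
session-arousal offset (SD 10 bpm).

**What is a person, and what is a walk.** The relative phases of harmonics
and axes are a *participant-level* gait signature: all walks of one
participant share them and differ only by a global time offset. This is the
load-bearing assumption for every null result. If phases were redrawn per
walk, the waveform shape itself would differ between walks, and any
classifier could separate two walks — hence "happy vs sad" — with no emotion
effect at all, since with one walk per emotion, walk identity and class label
coincide. Per-participant draws (dispersion controlled by a single knob,
`between_user_sd`, default 0.5): cadence (additive SD), amplitude and
harmonic weights (log-normal), walking heart-rate level (SD 40 bpm per unit,
i.e. 20 bpm at default), wrist-pose orientation (a random rotation applied to
both motion sensors, rotation-vector SD π·`between_user_sd` rad per axis),
and emotion-expression scales (below). With `between_user_sd = 0` every
participant is the identical population-mean walker.

**Emotion effects and their idiosyncrasy.** The nominal effect is: happy
+0.15 Hz cadence, ×1.15 amplitude, +6 bpm; sad the mirror image; neutral the
reference. Each participant expresses each effect channel with a log-normal
magnitude around the nominal value and an *idiosyncratic direction*: the sign
flips with probability `min(0.5, 5/3·between_user_sd)` (0.5 at the default,
i.e. direction fully idiosyncratic). This choice is deliberate and is what
makes three phenomena — all reported by studies of this kind — mutually
consistent: personal models are accurate (the effect is large within a
person), leave-one-user-out transfer sits at chance (the direction does not
pool), and cohort-level heart rate shows no consistent emotion effect. A
population-consistent direction cannot produce all three at once: with it,
pooled models recover the shared signal and transfer well above chance. The
corollary is that cohort-mean heart rate per emotion equals the population
set point regardless of the effect; the level-propagation property (cohort
mean tracks `hr_mean + d_hr`) is therefore tested with overrides pinning
consistent expression (`effect_scale_hr = 1`).

**Named configurations.** `null_cohort_config` zeroes the emotion effects
*and* disables drift, heart-rate persistence and the per-walk arousal offset.
All three are walk-level random effects; with one walk per class, any of them
separates the classes spuriously, so the chance-level expectation of a
type-I check only holds when windows are exchangeable across walks.
`hr_dominant_cohort_config` zeroes the motion effects (and drift) and doubles
the heart-rate effect, the regime for the importance-profile check.

**What the generator does not emulate.** Biomechanics (no gravity vector, no
gait events, no double-support structure), stimulus content, self-report
(PANAS) responses, sensor dropouts and timing jitter, and any within-walk
evolution of the emotional state. Passing tests show the *pipeline* behaves
correctly on data with the assumed structure; they are not evidence about
human affect.

## Neighborhood bias, measured honestly

With 50% window overlap, a held-out window shares 12 of its 24 samples with
training windows. On a zero-effect cohort this alone lifts random-CV personal
accuracy to ≈0.56 — pure evaluation bias, with no signal in the data. The
type-I property ("zero effect → accuracy ≈ 0.5") is therefore measured on
disjoint windows (step = length), where the null sits at 0.50; the
overlap-inflated figure is reported alongside it as a direct demonstration of
the bias, and the emotion-block scheme is the leakage-aware evaluation for
real (overlapping) feature matrices.

## Problem sizes and numerical choices

The study analogues run on 14-participant cohorts (16 for condition 1), ≈403
windows per emotion per participant — the original design's scale. Logistic
regression carries the repeated-CV analyses (10×10 folds); the random forest
runs with 2 repetitions where only it is needed (its accuracy figure and the
importance profiles), since 100-tree fits dominate runtime and the extra
repetitions change aggregates at the third decimal. Leave-one-user-out is
evaluated per condition cohort and averaged across the three conditions,
matching how such results are reported per condition; a single 14-user
cohort's LOUO mean carries ≈0.05 SD of cohort-composition noise, the
three-cohort mean ≈0.03. Randomness derives from one root seed: participant
substreams are keyed `[seed, participant, stream]`, and condition cohorts use
`seed·10 + condition`.

Degenerate inputs are handled by explicit convention rather than NaN:
zero-variance windows get skewness = kurtosis = 0; a zero-norm window-mean
vector maps to 90° angles; majority ties break lexicographically; all-zero
importance vectors and empty walk cuts raise. CSV I/O uses full-precision
floats with round-trip parsing, so write→read is bit-exact.

## Known limitations

- Personal-model accuracies on default synthetic cohorts (~0.99) sit at the
  top of, rather than across, the 62–99% per-user range such studies report;
  the effect-size and noise defaults trade realism of the *spread* for
  robustness of the qualitative contrasts the tests assert.
- The emotion-block scheme is defined for binary labels only; three-class
  problems use repeated stratified k-fold.
- The generator's heart-rate model (AR(1) + offsets) has no physiological
  dynamics (no recovery curves, no activity coupling).
- `FeatureMatrix` assumes one walk per (participant, emotion) when ordering
  windows for block CV; multi-walk sessions would need an explicit walk key.
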