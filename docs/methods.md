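# Methods

## The analysis model

The pipeline treats each subject's trial as a multi-keypoint kinematic time
series (position, velocity, acceleration in x, y, z per keypoint, 60
frames/s) and the TUG time as a continuous regression label.  All velocity
processing smooths each axis with a centred moving average (window 5 frames)
*before* magnitudes are taken; smoothing a magnitude would bias it upward
near zero crossings.  Window edges use shrinking (partial) windows so the
output length equals the input length and phase boundaries stay
frame-aligned.

Three projections are used throughout: the signed vertical component `z`,
the horizontal magnitude `xy = sqrt(x²+y²)`, and the full magnitude `xyz`.
Feature statistics are Max, Min, Mean and SD; the SD uses the population
denominator *n* (a fixed convention — with ~1500-frame trials the
distinction from n−1 is irrelevant, but tests and oracles must agree on
one).  "Min" of a magnitude projection is the minimum of the magnitude
(≥ 0); only z-direction statistics are signed.

Pelvis velocity variability (PVV) is the SD of the smoothed `xyz` pelvis
speed over all frames — column `xyz_SD_Vel_Throughout` of the 120-feature
table.  The coefficient of variation CoV = SD/mean is provided as a
companion variability measure (undefined, and rejected, for zero-mean
series).

## Phase segmentation

The pelvis z trace of a single-sit trial has a high plateau (standing,
including the walk-in), a monotone descent, a low plateau (sitting) and a
monotone ascent (standing up, including the walk-out).  Plateau levels are
estimated robustly as the medians of the top and bottom quartiles of z;
traces whose standing-to-seated range is below `min_amplitude` (default
0.15 m) raise "no sit detected".  A dual-threshold state machine with
hysteresis (`delta` = 0.15 of the amplitude) locates the descent and ascent
and rejects traces with more than one seated plateau.

Threshold crossings alone systematically lag the true plateau departure,
because a smooth transition leaves the plateau with zero slope: for a
smoothstep-like transfer of duration T, the 15%-depth crossing occurs about
0.24 T after onset — tens of frames for a slow transfer.  Each boundary is
therefore refined by least-squares fitting a minimum-jerk-style smoothstep
profile `z(t) = a + (b−a)·S((t−t0)/T)` to the transition region; the fitted
onset (and onset+duration for seat-on) are the reported boundaries, with the
raw crossings retained as a fallback and as brackets the refinement may not
escape.  On noiseless synthetic trials this recovers generator boundaries
exactly; with 5 mm Gaussian z-noise (after smoothing) boundary errors stay
within one or two frames.  Phases shorter than `min_phase_frames` (default
6 frames = 0.1 s) indicate a failed segmentation and raise.

## Feature selection and modelling

Within each of 5 cross-validation folds (shuffled, seeded, shared by every
model), features are z-scored using training-fold statistics only, and an
L1-penalized linear regression is swept over a descending log-spaced penalty
grid (100 points over [1e−3, 1e2]).  The grid point kept is the last one —
walking from the strongest penalty down — whose non-zero-coefficient count
is in [1, 3] before the count would exceed 3.  If near-duplicate features
make the count jump from 0 straight past the cap between adjacent grid
points, the first over-cap solution is trimmed to the three largest
coefficients by absolute value.  Frequency analysis counts selections across
folds; the final feature is the most frequent, with ties broken by mean
absolute coefficient and then lexicographically (all tie-breaks in the
package are deterministic and documented at the call site).

VIFs are computed per fold for multi-feature selections by regressing each
selected feature on the others with an intercept (statsmodels); 1−R² below
1e−12 is reported as infinite rather than an arbitrary large number.

The four comparison families are scikit-learn's LinearRegression,
RandomForestRegressor and SVR (with standardization) and xgboost's
XGBRegressor, all at library defaults with the fold seed — the comparison is
structural, not a tuning exercise.  The final univariate model is ordinary
least squares on the unstandardized feature, so the slope sign is directly
interpretable.  Aggregate metrics are reported two ways: the arithmetic
mean of per-fold MAE and Pearson r, and the pooled MAE/r over all
validation predictions.  The two differ slightly whenever fold sizes or
fold difficulty differ; both are written to every report.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes, not human
biomechanics.  Each virtual subject carries a latent physical-function
scalar f ∈ (0, 1] (cohort default: uniform on [0.25, 1.0], 60 subjects):

- **Peak walking speed** 0.6 + 0.9 f m/s — self-selected speeds from frail
  to preserved mobility.
- **Sit-stand transfer** parameterized by its peak vertical speed
  max(0.95 − 0.135/f, 0.22) m/s; like any timed movement measure this is
  taken affine in 1/f, so transfers lengthen hyperbolically (≈ 0.8 s fit,
  ≈ 2.7 s frail).  Standing and seated pelvis heights are 0.95 m and 0.50 m.
- **TUG label** = intercept + slope/f + Gaussian noise (defaults 4 s, 4 s,
  2.25 s).  Time on a fixed course scales with 1/speed, which reproduces the
  near-normal, right-tailed 6-to-20+ s TUG distribution.  The default noise
  was set with `tug_noise_for_target_r`, which inverts the attenuation
  relation r = ρ₀·sd(h)/sqrt(sd(h)²+σ²) by Monte Carlo so that the
  generative PVV-vs-TUG correlation is ≈ −0.7.
- **Trial composition**: walk in 2.5 m, pause, sit down, converse seated
  (9–11 s), stand up, pause, walk out, with four standstill pauses drawn
  uniformly from 0.2–2.0 s.  Positions are piecewise smoothstep
  (minimum-jerk-like) segments; velocity is the exact central finite
  difference of position, after which white Gaussian noise (default
  0.02 m/s) is added to velocity and acceleration channels.

Within-subject variation that real recordings would show, and that gives
the whole-trial SD its robustness advantage over single-phase or extreme
statistics, is modelled explicitly: each of the four movement bouts
(walk-in, sit-down, stand-up, walk-out) draws its own briskness multiplier
(walks N(1, 0.12), transfers N(1, 0.22)), and the walking speed carries a
per-subject gait modulation (relative amplitude uniform 0.05–0.30 at
1.2–2.2 Hz).  PVV integrates all bouts and so averages these fluctuations;
phase-restricted SDs see a single bout plus random pause composition, and
Max statistics are extremes of the modulated peaks.  This is the generator's
account of why the whole-trial xyz speed SD is the most label-informative
pelvis feature — a designed property that mirrors the structure the analysis
is meant to recover, not an emergent biomechanical fact.

Non-pelvis keypoints are the pelvis trajectory plus fixed anatomical
offsets, sinusoidal sway with per-subject random amplitude and rhythm
(spine small, limbs large) and band-limited positional jitter.  They are
plausible, correlated companions for the screening stage; the spinal
keypoints therefore screen close behind the pelvis and the extremities
fall off, but no limb dynamics are modelled.

SPPB component times follow the same latent scalar: balance holds are 10 s
minus an exponential deficit scaled by (1−f) (a small grace margin is
absorbed, so fit subjects complete the full hold), the 4 m walk is
4 m/speed, and the five-repetition chair stand scales with the transfer
time.  This reproduces the clinical ceiling effect — roughly half the
cohort scores a perfect 12 — that motivates regressing on TUG instead.

**What passing tests do and do not show.**  The generator omits turning,
step dynamics, sensor drift, soft-tissue artifacts and any true
biomechanics.  Recovery results on synthetic cohorts demonstrate that the
pipeline's inference chain is correct and stable under the assumed
statistical structure at the stated sample size; they are not evidence
about real patients.

## Problem sizes and numerical choices

The recovery experiment used by the test suite runs 20 independent cohorts
of 60 subjects (fold seed = cohort seed), a size at which the full chain
completes in well under a minute per cohort on one CPU.  Segmentation
accuracy is checked on 50 noiseless and 100 noise-perturbed trials spanning
the function-level range.  Lasso fits use scikit-learn's coordinate descent
(`max_iter` 1e5); smoothstep refinement uses `scipy.optimize.curve_fit`
with data-driven initial values, falling back to raw threshold crossings if
the fit fails.  Oracle-equivalence tests compare against direct-summation
implementations at 1e−12 (correlation, CoV, moving average), 1e−9 (SD
features) and 1e−8 (VIF).

## Known limitations

- The phase detector assumes exactly one sit and both plateaus present; it
  is validated only against the generator's ground truth.
- The CSV trial format is a documented in-package convention; vendor export
  formats are out of scope.
- Univariate aggregation conventions (mean-over-folds vs pooled) can
  diverge on small or unbalanced cohorts; both are always reported.
- SPPB interval endpoints follow the standard scoring sheet literally:
  "4.82–6.2 s" is left-closed, and exactly 8.70 s on the 4 m walk scores
  2 points because "more than 8.70 s" is read strictly.
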