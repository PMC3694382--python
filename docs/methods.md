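# Methods

This note records the model, the calibrations behind the synthetic
cohort, the numerical choices frozen in the extractors, and what the
synthetic conditions do and do not establish about real data.

## The two-stage health-index model

Per constitution (TE, SE, SY), stage 1 regresses the rater-averaged
VAS score on one diagnostic component's features:
`SHI_comp = α₀ + Σ α_j z_j`, where `z_j` are z-scored features (sample
SD, divisor n−1). Candidate features first pass a two-sample Student's
t-test at P < 0.2 between healthy (mean VAS ≥ 80) and unhealthy
subjects; the VAS ≥ 80 dichotomy is the same calibration that defines
the healthy category. The LASSO penalty is selected on a geometric
60-point grid from `α_max = max|Xᵀ(y−ȳ)|/n` down to `10⁻³ α_max` by
10-fold cross-validation at minimum mean squared error (a
one-standard-error rule is available via `rule="1se"`). Because the
response is left unscaled, coefficients read directly as VAS points
per z-unit, and the intercept of a fit on centered predictors equals
the group's mean VAS — which is why every published intercept sits
within a few points of its constitution's mean score.

Stage 2 applies the same machinery to the z-scored component scores
plus age and BMI, with two deliberate differences:

* **Stacked inputs.** Stage 2 is fitted on *out-of-fold* stage-1
  scores: each subject's component score is predicted by the stage-1
  model trained without that subject's fold. Fitting on in-sample
  scores lets stage-1 overfitting leak into the stage-2
  cross-validation; in our generative experiments that inflated the
  recovered R² by 0.10–0.18. The deployed models still use the final
  stage-1 fits on all data.
* **Relaxed LASSO.** The penalty only selects the support; the
  reported coefficients come from an unpenalized least-squares refit
  on it. An L1-penalized fit has no standard errors, and the published
  integrative table reports per-coefficient standard errors and P
  values, so a post-selection OLS refit is the only procedure
  consistent with that output. Stage 1 stays plain LASSO (its
  published tables show the many small shrunken coefficients
  characteristic of L1 estimates).

Accuracy is reported as pooled out-of-fold R² and adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1) with p the number of retained
predictors; training R² is reported alongside. CV folds are shuffled
with a fixed documented seed.

The bundled published models are frozen in a checksummed JSON file.
Their age/BMI coefficients were never published, so the bundled
integrative models cannot evaluate an absolute `SHI_sum`; the scorer
offers component-only evaluation or user-supplied `beta_age`/
`beta_bmi`. Published component models carry no training
normalization statistics either — their inputs must already be
z-scored, and the synthetic generator produces features on that scale.

## Synthetic cohort calibration

The generator's defaults are the study conditions: group sizes
100/72/126 (TE/SE/SY), per-constitution age and BMI normals, and
health-category probabilities equal to the published category counts.
Each subject draws, in order: a category; a true VAS inside the
category interval ([80,100], [40,80), [0,40), with a score of exactly
80 healthy and exactly 40 subhealthy); two rater scores; age and BMI;
and the five feature tables. One counter-based substream per subject
(`default_rng((seed, constitution, k))`) makes subject k invariant to
cohort size.

**Within-category VAS.** Default `"table7"`: a truncated normal per
category, all three sharing one parent normal per constitution whose
(μ, σ) are solved numerically so the category-weighted mixture
reproduces the published group VAS mean and SD exactly (TE 61.2±23.2,
SE 67.6±23.7, SY 74.3±19.9). A `"uniform"` mode samples uniformly in
the interval instead.

**Rater noise.** Both raters score the true VAS plus independent
Gaussian noise (clipped to [0,100]). The default SD of 5.2 points
follows analytically from the published inter-rater ICC of 0.95 and
the cohort's VAS variance (≈ 516 from the group means/SDs above):
σ = √(516·0.05/0.95) ≈ 5.2. Simulated cohorts then measure
ICC(2,1) ≈ 0.95 without further adjustment.

**Features (inverse-model generation).** For each component a
standard-normal vector x₀ (on the z-scale) is shifted along the
published coefficient direction a so that `a·x = (v − v̄_c) + ε`, with
ε ~ N(0, τ_c). The published model evaluated on the generated features
therefore returns the centered true VAS up to noise, and all
directions orthogonal to a stay pure noise. τ_c is calibrated so the
best linear read-out of the m informative components attains the
published integrative R² (0.58 TE, 0.65 SE, 0.38 SY):
τ_c² = m σ_d² (1−R²)/R², σ_d the constitution's VAS SD. SE has m = 3
(its published skin and voice models are intercept-only, so those
tables are pure noise and the pipeline drops their constant scores).
`feature_noise_sd` overrides τ_c; at 0 the published model reconstructs
the centered VAS exactly. Component residuals are drawn independently
across components — no joint covariance was published — so
cross-component feature correlations beyond the shared VAS signal are
absent, a knowingly unrealistic simplification.

**Questionnaire items.** Item-level responses (for the factor-analysis
path) are generated from the published 16-factor structure: k equally
loading items per factor with inter-item correlation
r = α/(k−(k−1)α) chosen to match the published Cronbach's alpha,
unassigned items as pure noise, latents discretized onto the 1–5
ordinal scale, every fourth assigned item reverse-coded. The
single-item "Unhealthy period" factor has no alpha (flagged, not
computed).

## Extractor conventions

Choices the source tables name but do not define, frozen here:

* **Complexion.** YCrCb is the full-range 8-bit BT.601 transform;
  sector SDs use the population divisor n; color correction is one
  affine 3-channel map on RGB fitted by least squares over ≥ 4 chart
  patches (rank-deficient patch sets are rejected). Sector masks are
  an input (label image of the seven atomic regions; the three "whole"
  sectors are unions of their parts by construction). Face
  landmarking is out of scope.
* **Pulse.** Beat onsets are the pre-upstroke local minimum; beats
  beyond ±25% of the median length are rejected; the dicrotic notch is
  the deepest local minimum 15–60% of the period after the systolic
  peak of the ensemble-averaged beat, with t4 referenced to the beat
  onset; HR75 normalization rescales time linearly by (60/75)/T, and
  the systolic/diastolic areas are trapezoidal integrals of the
  foot-referenced averaged beat split at the notch (their sum is the
  whole-beat area by construction). PDI is the depth of maximal pulse
  amplitude over the deepest applied depth; PVI is the half-maximum
  width of the amplitude–depth profile (linear interpolation)
  normalized by the applied-depth span, so a flat profile spans the
  whole domain (PVI = 1); PPW_PVI averages the amplitudes inside that
  interval. The PSD is Welch with a Hann window, four-beat segments
  and 50% overlap; the fundamental is the spectral peak nearest HR/60;
  the 10–50 Hz feature is the ratio of that band's integral to the
  0–10 Hz integral.
* **Voice.** F0 by normalized autocorrelation in 30–500 Hz with
  parabolic lag refinement, choosing the shortest lag within 75% of
  the in-range maximum (guards against period-doubling/octave
  errors); voicing threshold 0.45; frames 40 ms, hop 10 ms. Cycle
  marks are sub-sample-refined waveform peaks; cycle amplitude is the
  RMS level between consecutive fractional marks (one period's energy
  is phase-invariant, so perfectly periodic signals measure zero
  shimmer). Perturbation measures are MDVP-style (JITT/SHIM first
  differences; RAP 3-point, PPQ and APQ 5-point windows), in percent.
  Formants come from order fs/1000+2 LPC at 10 kHz in two passes:
  pre-emphasized (0.97) for frequencies, plain for bandwidths — the
  pre-emphasis zero systematically sharpens fitted pole radii, which
  would bias bandwidths low. sDT is duration × voiced-frame fraction;
  sF percentiles use linear interpolation; sFHL is flagged undefined
  when the F0 spread falls below the tracker's ~0.5 Hz resolution.
* **Skin.** Each suction cycle's hold-phase curve starts at the
  immediate elastic elevation (first sample); creep is the rise to the
  hold's end. E = E₁, E_hys = E₁ − E₃ (sign-free), V_E = creep₁/E₁
  (NaN at zero elastic response). Wrinkle fraction: multi-scale Sato
  line filter (σ = 1, 2) on the normalized grayscale image, Otsu
  threshold on the response — invariant to global brightness,
  monotone in true line coverage on the fixture family. The same
  algorithm serves the hand and arm sites.
* **Questionnaire.** Principal-component extraction; promax
  (Hendrickson–White, power 4) on a Kaiser-normalized varimax
  solution; items assigned at |pattern loading| ≥ 0.3 else dropped;
  factor scores are unit-weighted item means after reverse-coding,
  z-scored across subjects.
* **Agreement.** ICC(2,1) — two-way random effects, absolute
  agreement, single rater — is the default inter-rater form (both
  raters scored all subjects); ICC(3,1) via `form="icc3"`. One-way
  ANOVA uses the classical decomposition, with F exactly 0 for
  identical groups and flagged infinite at zero within-group variance.

## Raw-signal fixtures

The signal generators are simplified physical stand-ins aimed at
extractor correctness, not realism: the pulse beat is a clamped cubic
Hermite spline with zero-slope knots at the systolic peak, notch and
dicrotic lobe (so the notch position is exact by construction); the
vowel is a windowed-sinc glottal impulse train (fractional-sample
positions, so cycle lengths are not quantized to the grid) through
two-pole formant resonators; the sentence is a harmonic-rich tone
following a prescribed F0 contour; the face is flat Gaussian-perturbed
sectors with an in-frame chart and an optional global linear color
distortion; wrinkles are straight dark lines with a known ground-truth
mask. Audio I/O is 16-bit PCM mono WAV at 44.1 kHz; images are 8-bit
PNG.

## What the synthetic conditions show — and don't

Passing tests establish that the pipeline is internally consistent:
extractors invert their generators, the model recovers generative
structure at the published signal strengths, and the agreement
statistics match their analytic calibrations. They do not establish
that the published models generalize to any real population, that the
feature extractors match the original devices' proprietary
processing, or that the linear-Gaussian feature model mimics real
biological covariance (components are conditionally independent given
VAS here). The study population itself was women aged 50–75; nothing
here extends beyond it.

## Problem sizes

Default checks run at the study's own scale: 298-subject cohorts, 50
replicates for agreement/calibration averages, 20 replicates for the
full two-stage recovery experiment, n = 1000 subjects for the
factor-structure recovery simulation and n = 10⁴ for category
proportion convergence. These sizes keep every result's Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

* The bundled integrative models cannot produce absolute `SHI_sum`
  values (unpublished age/BMI terms); all absolute-scale claims are
  limited to component scores.
* The tonometry indices follow a documented normalized-profile
  interpretation; the original device's definitions are not public.
* Glossiness cannot be separated from pallor by the complexion
  statistics, so no gloss feature is attempted.
* Measured jitter on the vowel fixtures is attenuated (~0.8×) relative
  to the injected cycle perturbation because resonator ringing from
  the previous cycle pulls the next cycle mark; monotonicity, not
  unbiasedness, is the tested property.
* The recovered cross-validated accuracy of the honest (stacked)
  pipeline sits systematically below the generative R² — the expected
  behaviour of an unbiased estimate versus an in-sample one.
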