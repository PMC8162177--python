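# Methods

## The generative face space

The synthetic space mimics the structure of a morphable face model: a face
is a categorical average plus an identity residual through orthonormal
bases.

- **Cells.**  One average mesh and texture per ethnicity × sex cell at a
  fixed age.  The base head is an ellipsoid (radii 90/110/100 mm) sampled on
  a golden-spiral lattice; each cell deforms it by a smooth low-order
  polynomial radial field and tints a low-pass random L\*a\*b\* texture
  around a skin-tone baseline (L\*≈62, a\*≈14, b\*≈16).  Cells therefore
  differ by smooth, reproducible deformations, as ethnic averages do, but no
  claim of anatomical realism is made.
- **Shape basis.**  A column-orthonormalized Gaussian matrix,
  (3·n_vertices) × n_shape_dims.
- **Complexion bases.**  One basis per spatial-frequency band.  Gaussian
  textures are masked in the FFT domain to an octave annulus (band 0 is the
  coarsest and includes DC) and then orthonormalized; because
  orthonormalization preserves the column span, every basis column is
  exactly band-limited.  The construction fails loudly if the requested
  dimensionality exceeds the annulus's real dimension.
- **Coefficient law.**  Identity coefficients are independent zero-mean
  Gaussians with a PCA-like decaying scale σⱼ ∝ (j+1)^−0.6 (shape amplitude
  15 mm-scale, complexion amplitude 8 L\*a\*b\* units, per-band attenuation
  0.75^band).  The morphable-model literature does not pin down a sampling
  law for "random coefficients"; independent Gaussians with a decaying
  spectrum are the PCA-natural choice.

Default desk scale is 500 vertices, 40 shape dimensions, an 80×60 texture
grid, and 40 complexion dimensions × 5 bands; the full-scale geometry
(4,735 vertices, 467 dimensions, 800×600, 5 bands) is expressible through
the same config.

## Simulated raters

A rater's drive for a stimulus is the inner product of a planted preference
with the stimulus coefficients, plus Gaussian noise whose SD is set from a
target drive signal-to-noise ratio (default SNR 2, in SD units).  Drives map
to the 9-point scale by empirical quantiles into nine equal-count bins (ties
broken by trial order; a constant drive collapses to the midpoint).  This
guarantees full scale use and a monotone, near-linear coefficient–rating
relation.  Viewpoint (−30/0/+30°) cycles across trials and never affects
ratings; it is carried as a nuisance column only.

**Preference sampling.**  Planted preference weights are iid Gaussians per
dimension, *independent* of the coefficient scales, so preference drive is
dominated by the leading identity components — the components that dominate
visible face variation.  (An earlier design weighted dimensions by 1/σⱼ to
equalize per-dimension drive variance; that spreads signal over all
dimensions so thinly that the regression target is barely identifiable at
1,950 trials, and it plants implausibly large weight on near-invisible
components.)

**What the recovery target is.**  The reverse regression estimates
cov(coefficient, rating) per dimension; for Gaussian coefficients and any
monotone rating link, Stein's lemma gives the population slope direction as
wⱼσⱼ² — the preference *scaled by the coefficient variances* — not w itself.
All recovery cosines are therefore computed against
`expected_slope_direction(w) = w ⊙ σ²`.  Comparing raw w is only meaningful
for uniform scales.

## Fitting

Each dimension (and, for local models, each vertex coordinate and each
down-sampled pixel channel) is regressed on the raw integer ratings by
iteratively reweighted least squares with Tukey bisquare weights: tuning
constant 4.685, MAD/0.6745 scale with leverage-adjusted residuals, at most
50 iterations, relative tolerance 1e-8.  The two-parameter design admits a
closed-form weighted solve, so all dimensions run simultaneously — one
participant's 240-dimension fit at 1,950 trials takes ~0.2 s.  Slope
standard errors use the converged weighted fit with df = n−2; columns with
(near-)zero robust scale freeze at the least-squares solution.  Degenerate
inputs (constant ratings, <10 trials, non-finite coefficients) raise typed
errors.

Local-model p-values are corrected by Benjamini–Hochberg at q = 0.05,
jointly across all vertex-coordinate tests and, separately, jointly across
all pixel-channel tests (textures are block-mean down-sampled by 4 per axis,
the 800×600 → 200×150 ratio).

**Linearity diagnostic.**  Ratings collapse to 5 bins {1–2, 3–4, 5, 6–7,
8–9} (bin edges are a package choice; only the bin count is canonical).  The
per-bin mean face is rendered (by affinity, the render of the mean
coefficients), and its per-vertex deviation from the cell average is taken
*signed* — projected on the vertex's outward radial direction — because a
linear preference drives bin means from one side of the average to the
other, and an unsigned distance would fold into a V shape regardless of
linearity.  Rows are clustered by k-means (20 restarts, fixed seed) with k
from the elbow rule on within-cluster dispersion over k = 1..8.  Note that
even a perfectly linear rater shows a small intrinsic S-curvature: the
bin-conditional means of a Gaussian drive under equal-count bins are
truncated-normal means (≈ ±1.34, ±0.44, 0), about 8.6 % away from a
straight line.

**MI cross-check.**  Gaussian-copula MI (rank-normalize both variables,
−½ ln(1−ρ²) on the transformed data), signed by the robust slope.  It is
parameter-free and robust; a histogram plug-in estimator serves as the
independent oracle in tests.

## Feature analyses

- **Group models** average β₁/β₂ elementwise; by linearity of rendering,
  the render of the mean equals the mean of renders.
- **Extreme faces** render the cell average ± gain·β₂ with default gain 4
  (the rating extremes, ±4 steps from the scale midpoint).
- **Z-scored attractive features** pool each rater's top-rated stimuli
  (default rule: ratings ≥ 8, falling back to the rater's top decile), take
  the per-dimension modal coefficient by Gaussian-KDE peak (Silverman
  bandwidth, 512-point grid), render the modal face, and z-score it against
  per-location moments of the full stimulus set.  Zero-SD locations are
  flagged NaN, never silently zeroed.  Under a *linear* rater the modal
  face is capped near E[drive | top bin] (≈1.3–1.7 SD); the >1.5 SD
  "outskirts" extremity reported for real observers reflects genuinely
  peak-shifted preferences, which this generator deliberately does not
  emulate — tests assert against the analytic cap and a null baseline
  instead.
- **Dimorphism** is the female-minus-male average difference per ethnicity,
  reparametrized through the bases; reduced dimension sets keep the leading
  dimensions selected by the elbow rule on the coefficient-scale spectrum
  (the generative model's eigenvalue analogue), per band for complexion.
- **The bootstrap cosine test** compares the reduced-dimension β₂ with the
  reduced dimorphism direction; the null is the distribution of cosines
  between bootstrap refits (trials resampled with replacement) and the
  original model, and the preference is declared different from dimorphism
  below the null's 2.5th percentile.  The test is scale-invariant and
  calibrated: at 1,950 trials a preference planted *equal* to the direction
  is rejected in ≈0 of 20 runs, an orthogonal one in ≈20 of 20.  At much
  smaller trial counts the test over-rejects slightly (the bootstrap null
  scales deficits by ‖β₂‖² > ‖signal‖²).

## Representation space and variance decomposition

Individual models are vectorized at vertex (shape) and down-sampled pixel
(complexion) granularity, mean-centered across models (variables unscaled),
and decomposed by SVD; the kept count is the elbow of the eigenvalue curve
(largest perpendicular distance to the chord, ties to the smallest index).
Per component, with scores measured from 0 (the no-preference point):

    R2_group       = 1 − SSresi1/SStotal
    R2_participant = SSresi1/SStotal · (1 − SSresi2/SSresi1)

where SSresi1 removes condition means and SSresi2 further removes
participant means of those residuals; SSresi2/SStotal + R²g + R²p = 1 holds
to 1e-10.  Overall shares weight components by variance explained.

Permutation thresholds: in group mode, participants move as blocks (each
participant's bootstrap models stay together) across conditions; in
participant mode, participant labels shuffle within condition.  Each
component's threshold is the (100 − 100α/k) percentile of its null
(one-tailed Bonferroni over k components: 99.375 for 8 components, 98.33
for 3); the overall threshold is the variance-weighted sum of the
per-component thresholds.  Family-wise group significance fires at ≈3–8 %
of no-effect simulations at nominal 5 %.

Transferred-vs-interactive classification is per vertex coordinate / pixel
channel on group models mapped to those spaces: *transferred* where the
other-ethnicity model's sign matches the own-culture own-ethnicity model,
*interactive* where it matches the other culture's, *both*/*neither*
accordingly; zero slopes (sign 0) match nothing, and overlapping locations
are reported as their own class rather than double-counted.

## Validation

Trials are randomly segmented into 13 contiguous blocks under a recorded
seed.  Per fold, the rater's model is refitted on training trials, the
attractiveness space is rebuilt from that model plus all context models,
each stimulus's rendered identity residual is projected onto the kept
components, and a Gamma GLM with log link (IRLS, max 100 iterations,
tol 1e-8) predicts the positive, right-skewed ratings; held-out performance
is Kendall's τ.  Non-converged folds are flagged, never silent.  Alternative
predictors run through the same GLM: averageness (Euclidean norm of the
stimulus's coefficient vector) and dimorphism (scalar projection onto the
reduced direction).  Paired comparisons use the participant's mean τ across
folds as the unit (folds within a participant are dependent), Bonferroni
over the four tests.

## Problem sizes

Study-condition scale — desk-scale space, 1,950 trials, drive SNR 2, 20
raters per condition (80 total) — is used for parameter recovery and the
representation-space summaries.  Calibration and cross-validation studies
use a reduced space (60 vertices, 8 shape dims, 6 complexion dims × 3
bands, 48×64 grid) with 150–1,950 trials and 8-rater cohorts, chosen so the
full statistical designs (hundreds of simulated cohorts, bootstrap and
permutation loops) complete in minutes while every null calibration keeps
its nominal level.

## Known limitations

- The generator's linearity is an assumption *and* a construction: raters
  whose preferences are nonlinear or peak-shifted (the interesting empirical
  case) are out of its vocabulary, so passing tests demonstrate correctness
  of the machinery, not adequacy of the linear model for real observers.
- The synthetic geometry and textures carry no anatomical content; vertex-
  and pixel-level maps are meaningful as statistical objects only.
- Gaussian-copula MI is exact for monotone relations but underestimates MI
  for non-monotone ones; the signed-MI model inherits the regression slope's
  sign and is zero-signed where the slope is exactly zero.
- The bootstrap cosine test's self-similarity null narrows as trials grow;
  with very few trials it over-rejects mildly (see above).
- Ratings are treated as exchangeable across the session; drift, fatigue and
  block effects present in real experiments are not modeled.
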