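# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the validation suite shows.

## The analysis model

**Connectedness.** For a subject with residual time series `x_v(t)` at
gray voxels `v = 1..N`, each voxel's connectedness is the Fisher-z of its
mean Pearson correlation with the *other* voxels:
`z_v = atanh( (1/(N-1)) sum_{u != v} r(v, u) )`. With every series
demeaned and scaled to unit L2 norm, `r(v, u)` is an inner product and the
map is computed as `(x_v . S - 1)/(N - 1)` with `S` the sum of unit
vectors — identical to the pairwise double loop to 1e-8 (tested). The
transform is applied to the mean r (the map-level reading); averaging
Fisher-z values of individual correlations instead is available behind the
`z_before_average` flag. GCOR — the mean of all `N²` pairwise
correlations, self-pairs included — equals the squared norm of the mean
unit vector and is therefore always nonnegative; the identity with the
raw pairwise mean is exact and tested.

**Group model.** With exactly one observation per subject and no
within-subject factors, a linear mixed model for a 2x2 between-subject
design reduces exactly to OLS, so the interaction map is fit by
vectorised OLS: `y = b0 + b1 dx + b2 sex + b3 dx*sex + b4 age + b5 motion
+ b6 GCOR`, with `dx, sex` effect-coded as -1/2 (TD, F) and +1/2 (ASD, M).
Under this coding `b3` is the difference of differences
`(ASD_M - TD_M) - (ASD_F - TD_F)` directly; covariates are mean-centered
and the interaction inference is invariant to the centering shift
(tested). Tests are two-sided throughout: a crossover has no a-priori
sign. Constant covariate columns are dropped (a centered constant is
all-zeros). Within-sex ASD-TD contrasts refit the covariate-adjusted
model inside one sex.

**Nuisance regression.** Each gray voxel's design contains a 4th-order
Legendre baseline, six motion parameters, the mean ventricle series, any
externally supplied physiological regressor columns, and a voxel-specific
white-matter regressor: the mean over eroded-WM voxels whose centers lie
within 15 mm of the target voxel (global WM mean as a logged fallback when
the sphere is empty). Nuisance columns are detrended against the baseline
before fitting. The shared columns are projected out via an orthonormal
(SVD) basis — rank-deficient designs drop dependent columns with a
warning — and the voxel-specific WM column is then removed by exact
Gram-Schmidt, so residuals are orthogonal to every design column at every
voxel (tested at 1e-8 relative). Scaling to percent signal change
(x / temporal mean x 100, near-zero-mean voxels masked out) happens before
regression; regressors are extracted from the unsmoothed scaled data and
the regression is applied to the smoothed scaled data, whose residuals
feed all connectivity stages. Motion regressors enter in native units
(degrees, mm); the motion *summary* converts rotations to arc length on a
50 mm sphere (configurable) and averages the Euclidean norm of the
six-parameter first difference, in mm/TR.

**Cluster inference.** The spatial ACF of the group-model residual maps is
estimated from lag correlations along the three axes (volumes
standardised within the mask, lags pooled by distance) and fit by least
squares with the Gaussian-plus-exponential mixture
`ACF(r) = a exp(-r²/(2b²)) + (1-a) exp(-r/c)`, `a in [0,1]`, `b, c > 0`
(pure-Gaussian fallback on fit failure). Null fields with this ACF are
synthesised by spectral shaping: the target autocovariance kernel is laid
out on the periodic bounding box with minimum-image distances, transformed
to a spectral density, negative values clipped to zero (logged), and a
white field is filtered by its square root; fields are standardised within
the analysis mask. The cluster-size threshold is the smallest integer k
with Monte-Carlo `P(max null cluster >= k) <= alpha`, under two-sided
voxel thresholding at the Gaussian quantile for `voxel_p` and face-only
(NN1) connectivity — the most conservative choice; the `df` argument
records the t-map df used when thresholding real maps. Small-volume
correction passes the cerebellar sub-mask instead of the whole-brain mask.
Post hoc seed spheres (6 mm) are placed at surviving cluster peaks (ties
broken toward the lowest linear index, logged; edge spheres clipped), and
seed-map interaction tests are cluster-corrected at `alpha / n_seeds`.

**Region matrices and similarity.** Region-mean residual series yield
15x15 Fisher-z matrices (correlations clipped to ±(1 - 1e-7) before
arctanh so degenerate inputs stay finite; the diagonal is excluded and BH
runs over the 105 unique pairs only, never the duplicated triangle). The
realized BH p-threshold (largest rejected p) is reported next to q at both
the interaction stage and the within-sex stage, which is restricted to the
interaction-surviving pairs. Similarity vectors are the Fisher-z values
over the surviving pairs; each ASD subject is compared to the TD-male and
TD-female mean patterns by Pearson correlation (invariant to mean shifts —
pattern only) and Euclidean distance (pattern plus magnitude). When a
subject is compared against their own group's reference the mean is
recomputed without them (leave-one-out; self-similarity bias). The two
similarity series are compared by a paired t-test when Shapiro-Wilk at
alpha = 0.05 does not reject normality of the differences, otherwise by
the Wilcoxon signed-rank test (logged). The 4x2 descriptive distance
table covers all four cells; paired between-group comparisons whose
pairing scheme is not derivable from the cell sizes are deliberately not
implemented.

## The synthetic cohort generator

The generator emulates the study conditions: four cells of 23 (ASD-F),
56 (ASD-M), 24 (TD-F) and 65 (TD-M) subjects; 137 volumes at TR 3.5 s on
a 20x24x20 grid of 3 mm voxels; two "cerebellar" regions in a low-z
compartment and thirteen "cortical" 6 mm spheres, pairwise disjoint; gray
matter as a 9 mm halo around the regions, a ventricle block, and white
matter filling the rest of the brain box.

**Couplings.** Region signals are `L @ N(0, I)` with `L` the Cholesky
factor of the planted correlation matrix `C = tanh(Z_cell)`, so the model
correlation of every pair equals `tanh(z)` exactly (for one coupled pair
this is the shared-component construction with weight `sqrt(r)`).
Defaults, on the Fisher-z scale: cerebellar-cortical planted pairs at
0.35 ± delta with delta = 0.15 (+ for ASD-F, - for ASD-M, TD at
baseline — the crossover; the planted interaction contrast is
-2 delta = -0.30); cortico-cortical 0.25; the two cerebellar seeds 0.25;
unplanted cerebellar-cortical 0.20. Seed R couples to cortical regions
1-6 and seed L to 7-13 (13 planted pairs). These values were chosen once
so that all four cell matrices are positive definite with margin
(minimum eigenvalue 0.08 at +delta) and recovery is reliable at desk
scale; non-PD or |r| >= 1 requests raise.

**Nuisance structure** (all in percent-signal units on a 1000-unit
baseline): per-subject random 4th-order Legendre drift (sd 1.0 per
order); a global signal added to all gray voxels (sd 0.3); four
white-matter artifact sources with 6 mm Gaussian spatial profiles (which
bleed into nearby gray — exactly what the localized WM regressor is for)
and AR(1) time courses (sd 1.0); motion as a slow random walk with
step-like spikes (rate 0.03/volume) whose spatial artifact is linear in
the motion parameters (gain 0.5); i.i.d. noise (sd 0.5); then 6 mm FWHM
Gaussian smoothing. Ages and IQ are drawn identically across cells so
Kruskal-Wallis matching holds by construction (a mismatched mode exists
for negative testing). All randomness descends from per-subject seeds
spawned off one root seed: any access order reproduces the cohort
bitwise.

**Fast tiers.** `simulate_region_cohort` emits region-mean series only,
for matrix-stage studies at scale; its GCOR covariate is computed from
the closed form of the voxel-level GCOR (region/background voxel counts,
realized region correlations, a per-subject global-signal amplitude),
because the naive 15x15 matrix mean makes GCOR an order of magnitude more
collinear with the planted interaction than it is at voxel scale and
produces spurious cortico-cortical discoveries under covariate
adjustment. `simulate_pattern_cohort` draws similarity-stage pattern
vectors directly; its gender-incoherence mode separates the TD sexes by a
per-pair signature (magnitude 0.15) and places the ASD-female mean a
third of the way from the midline toward TD males — distance ratio 2:1
(TD-female : TD-male), with the ASD-male mean at the TD-male mean —
because under the pure crossover default the two TD reference patterns
coincide in expectation and there is no similarity preference to detect.

**What the generator does not emulate:** hemodynamic-response
convolution, cardiac/respiratory waveforms (physio regressors enter as
precomputed columns), scanner drift nonstationarity, registration error,
anatomical variability, or atlas space (all coordinates are voxel-grid
indices). Passing tests therefore show that the *pipeline* recovers what
was planted under realistic nuisance structure at desk scale — not that
any particular real-data finding replicates.

## Validation scales and observed behaviour

The test suite and `scripts/acceptance.py` compute, at these scales:
type-I error of the voxel-wise interaction test pooled over 200 null
cohorts x 9600 i.i.d.-voxel maps (binomial interval around 0.005);
cluster FWE over 500 fresh null fields against a threshold estimated from
1000 (within 0.05 ± 0.02); null false-discovery proportion of the
105-pair BH step over 500 region-level cohorts; cluster/crossover
recovery over 20 full-pipeline cohorts at the study's cell sizes (the
acceptance script uses 6 cohorts and reports the same estimator); and
similarity detection over 50 pattern cohorts. One full 168-subject cohort
runs end to end in ~30 s on one CPU.

## Numerical choices and edge cases

Correlation clipping at ±(1 - 1e-7) before arctanh; coverage masks use an
inclusive bound with a 1e-9 tolerance so exact fractions (17/20 at 0.85)
are included; erosion is 6-connected with the volume border treated as
background; sphere membership is `distance <= radius` between voxel
centers in mm (0-based indices); zero-variance voxel series are dropped
from masks with a warning; a residual variance at rounding level relative
to the data yields t = 0, p = 1; empty cluster reports and empty survivor
sets are valid outputs, not errors; subject synthesis accumulates in
float32 (seven significant digits, far beyond BOLD dynamic range) while
all statistics run in float64.

**A caveat on unequal reference groups.** The Euclidean distance of a
probe vector to a *sample* reference mean includes the reference mean's
own sampling variance (order `n_pairs * sigma² / n_ref`).  With unequal
TD reference sizes the expected distance to the smaller reference group
is therefore slightly larger even under an exchangeable null — the paired
test picks this up at above-nominal rates when the reference groups
differ several-fold in size.  The null-calibration test uses equal-size
references for exactly this reason; results of the distance comparison on
strongly unbalanced reference groups should be read with this bias in
mind (the correlation measure is much less affected).

## Known limitations

Whole-run polynomial baselines only (single continuous run); no
despiking, censoring, slice-timing or registration; Monte-Carlo cluster
p-values only (no random-field theory); no partial correlation, windowed
connectivity or graph metrics; the df-143 style paired comparisons of the
descriptive distance table are not reproduced (pairing undefined); atlas
mapping of peak coordinates is left to the user.
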