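# Methods

This note records the models, conventions and numerical choices behind
habikit, and what its synthetic experiments do and do not establish.

## Image model and preprocessing

Cases are dual-phase (arterial/venous) CT volumes with one binary tumor
mask, all on a single grid; inter-phase registration is an upstream,
external step and the package only *verifies* grid agreement (shapes,
spacings and origins within 1e-6 mm), raising a named alignment error
otherwise.  Arrays are (z, y, x), 0-based, voxel-center coordinates.  The
working spacing is 5 × 1 × 1 mm (z, y, x); resampling uses cubic B-spline
interpolation for intensities and nearest-neighbour for the mask, which is
re-binarized at 0.5.  A case whose mask vanishes after resampling is an
error, not an empty result.

Gray levels are discretized with a fixed bin width of 25 HU anchored at
the region minimum (IBSI "fixed bin size"): level(x) = floor((x − min)/25)
+ 1.  Discretization is computed per region — whole tumor and each habitat
separately — because each region is an independent feature source.  This
makes every texture feature invariant to adding a constant HU offset, a
property the test suite checks.  Clustering, by contrast, uses raw HU
voxel vectors (both phases are on comparable HU scales and subregion
semantics rest on absolute enhancement differences).

## Habitat clustering

Each tumor is clustered independently (per-case, not pooled across
patients): K-means (k-means++, n_init = 10, max_iter = 300, tol = 1e-4,
seeded) on the n × 2 matrix of (arterial, venous) HU.  The cluster count
is chosen by maximizing the Calinski–Harabasz score over k = 2..10, ties
to the smaller k; perfect separation (zero within-cluster dispersion)
maps to +inf so it wins any comparison.  Labels are then permuted so that
subregion 1 has the largest mean arterial + venous HU (ties: arterial
mean, then cluster size).  Cross-patient correspondence therefore comes
from enhancement rank, not from any spatial registration.  The pipeline
default fixes k = 3 — the configuration the cluster-count experiment
selects on three-population phantoms — while `select_k` remains available
per case, and a cohort-level selection can average per-case CH curves.

## Radiomics features

Counts per region and phase: 18 first-order, 14 shape (whole tumor only),
73 texture.  The 18-feature first-order set excludes standard deviation
(redundant with variance); entropy and uniformity use the discretized
levels, every other first-order statistic uses raw HU; moments are
population moments (kurtosis is not excess-corrected) and zero-variance
regions return skewness = kurtosis = 0.

The 73-texture composition is GLCM 22 + GLRLM 16 + GLSZM 16 + GLDM 14 +
NGTDM 5.  The GLCM 22-set is the modern 24-feature list minus SumAverage
(equal to 2·JointAverage for symmetric matrices) and MCC; the exclusions
are config-visible so an alternative 73-set can be declared.  All matrices
use unit distance and 26-connected 3-D neighbourhoods on the anisotropic
grid, without distance weighting: GLCM symmetric and averaged over the 13
unique direction pairs; GLRLM averaged over the same 13 directions; GLSZM
zones by 26-connectivity; GLDM with dependence threshold α = 0 where the
dependence size counts the center voxel (sizes 1..27, which keeps the
small-dependence emphases defined); NGTDM uses the mean level of in-region
neighbours.  Degenerate single-level regions return defined values (GLCM
contrast 0 and correlation 1, one GLSZM zone, NGTDM contrast 0).

Shape features are mesh-based: marching cubes on the padded mask indicator
pre-smoothed with a Gaussian of 0.6 voxels.  Plain marching cubes on a
binary field overestimates the area of digitized smooth surfaces by ~9%
(staircase bias; a 10 mm digital sphere gets sphericity 0.91 instead of
~1); the sub-voxel smoothing restores accuracy for smooth solids
(sphericity 0.976 on that sphere) at the cost of rounding genuinely sharp
edges (a 10 mm cube's area reads ~10% low).  Tumors are smooth-ish blobs,
so the smooth-solid regime is the relevant one.  Axis lengths come from
PCA of the physical voxel coordinates (axis = 4√λ); maximum diameters from
convex-hull vertices of the mesh.  Single-voxel masks fall back to
voxel-based values with a warning.

Feature columns are named `{phase}_{region}_{family}_{feature}` (for
example `A_sub1_firstorder_Mean`), in a fixed order: 210 whole-tumor (CR),
546 subregion (HR), 756 combined.  Subregions below 5 voxels are computed
but flagged `small_region`.

## Screening and modelling

Normalization defaults to min-max to [0, 1], fit on training rows only and
reapplied unchanged to validation/test rows (values outside [0, 1] are not
clipped); z-score is a config switch.  Constant columns pass through as 0,
flagged.  The screening chain is: ICC(2,1) (two-way random, absolute
agreement, single measurement) ≥ 0.75 across two readers' feature tables
when a second segmentation exists; per-column univariate screen choosing
the t-test when both classes pass Shapiro–Wilk (p > 0.05) and the
asymptotic tie-corrected Mann–Whitney U otherwise, keeping p < 0.05;
greedy Spearman pruning of pairs with |ρ| > 0.9 (visiting pairs by
decreasing |ρ| and dropping the member with the larger mean absolute
correlation, ties to the later name); and L1-penalized logistic regression
over a 20-point C-path chosen by stratified 10-fold CV with the
one-standard-error rule.  An all-zero solution falls back to the ten
smallest univariate p-values, flagged.  Every threshold is config-exposed
and every step logs its input/output counts.

Six classifiers are supported; the SVM uses an RBF kernel with explicit
Platt scaling — a logistic sigmoid fit on the training decision values —
so probability scores are strictly rank-preserving with respect to the
margin (scikit-learn's internal cross-validated Platt can invert rankings
on small cohorts).  Hyperparameters are tuned by stratified k-fold CV by
mean AUC; the nominal 50 folds are capped at the minority-class count
(with a warning) so stratification stays possible.  The operating point is
the training-score threshold maximizing Youden's J, candidates at
midpoints of adjacent unique scores, ties to the lower threshold;
prediction calls positive at score > cutoff (strict), so a score exactly
at the cutoff is negative.  The cutoff is fixed on training scores and
reused unchanged downstream.

## Statistics

AUC uses midrank ties and equals Mann–Whitney U/(n₁n₀) identically (a
property test enforces the identity).  CIs and the paired test use the
DeLong placement-value covariance with a normal approximation, CIs clipped
to [0, 1]; identical score vectors short-circuit to z = 0, p = 1.  McNemar
on paired accuracies uses the exact two-sided binomial when the discordant
count b + c < 25 and the continuity-corrected chi-square otherwise.
Hosmer–Lemeshow bins by deciles of risk (quantile edges, ties merged);
df = bins − `fitted_params`, default 2 (the classic convention for
probabilities fit on the same data).  For externally supplied
probabilities no parameters were estimated and the correct null is
chi-square with g degrees of freedom, so the calibration-null simulations
pass `fitted_params=0`; with the default the test over-rejects by ~6% at
the 5% level in that setting.  Decision curves use NB(t) = TP/n −
(FP/n)·t/(1−t) with calls at prob ≥ t (note: the DCA thresholding is ≥ by
convention, independent of the model's strict-> call rule), plus treat-all
and treat-none references.  Average precision is step-wise without
interpolation.  Fleiss' kappa comes from the standard category-proportion
formula (via statsmodels), with a single-category input treated as
undefined.  Baseline-table tests: Pearson chi-square without continuity
correction for r×c counts; ANOVA (default) or Kruskal–Wallis for 3-group
locations; Welch/pooled t or Mann–Whitney for 2 groups.

## Explanations

Shapley attributions use the kernel estimator with the
marginal-expectation value function over a background set (up to 50
medoid-sampled training rows, seeded).  For d features, all 2^d − 2 proper
coalitions are enumerated when feasible (making the estimate exact, which
the tests verify against factorial-weighted coalition enumeration for
d ≤ 8); otherwise coalitions are sampled by the size-aggregated kernel
distribution, requiring n_samples ≥ 2d + 2.  The local-accuracy constraint
(base value plus contributions equals the model output) is enforced
exactly by constrained least squares.  Attributions explain the
probability-scale output, so positive values push toward LNM-positive.

## Reader study

Reader calls are consensus over exactly three repeats (majority vote);
Node-RADS scores binarize at ≥ 3.  Round-2 vs round-1 comparisons use the
paired DeLong test on the binary calls treated as two-point ROC scores
(reader AUC = (sensitivity + specificity)/2) and McNemar on accuracy.
Per-score metrics report nulls, never zeros, for undefined quantities in
small strata.  Sankey data traces score → model call → outcome with
reclassified-positive (score 1–2, model call 1) and reclassified-negative
(score 3–5, model call 0) flows; link conservation at the model nodes is
an invariant.

## Synthetic data: what it emulates, and what it does not

Phantoms are ellipsoids on a CT-like grid (default 12 × 48 × 48 voxels at
5 × 1 × 1 mm, radii 15/14/14 mm ≈ 2,500 voxels) whose in-mask voxels are
drawn from three bivariate-Gaussian populations with arterial means
150/90/30 HU, venous means 130/100/45 HU and SD 12 HU (≥ 5 SD separation),
fractions 0.40/0.35/0.25, clipped to [−200, 400] HU.  The concentric
layout fills shells from the core outward in population order (population
1 core-to-middle, population 3 at the rim), mirroring the enhancement
geography of real habitat analyses; a blob layout with
capacity-constrained nearest-seed assignment provides harder clustering
problems.  Population voxel counts match fractions to within one voxel by
largest-remainder rounding.

Cohorts draw per-case population fractions from a Dirichlet (concentration
60 about the default fractions), population-1 arterial enhancement from
N(150, 12²), and tumor radii scaled by U(0.85, 1.15).  The label follows a
logistic link on two standardized covariates — the population-1 fraction
and its enhancement — with the intercept solved so expected prevalence
matches the requested value (default 0.59, the positive rate of the
motivating training cohort).  The "strong" effect uses slope 4 per SD on
each covariate; the null effect uses 0.  Reader simulation operates at the
call level: empirical readers hit with their nominal
sensitivity/specificity per repeat; RADS readers draw a Node-RADS score
from a conditional 2 × 5 distribution and their call is the binarized
score.

Passing tests on these phantoms shows the machinery is wired correctly —
cluster-count recovery, count conservation, signal recovery and honest
nulls — not that habitat radiomics works on real CT: the phantoms have no
scanner noise texture, partial-volume mixing, registration error,
segmentation variability or realistic tumor morphology, and reader
behaviour is reduced to flip probabilities.

## Problem sizes and determinism

The recovery experiments run the full pipeline (clustering → 756 features
→ screening → SVM → held-out evaluation) on cohorts of n = 250 (strong
effect) and n = 120 (null) over 10 seeds each, with 10-fold CV tuning;
the cluster-count experiment uses 20 phantoms; DeLong type-I error uses
2,000 paired null replicates at n = 100; calibration nulls use 100 seeds
at n = 1,000.  These sizes keep the whole suite desk-scale while leaving
the binomial/normal error of each checked proportion well inside its
acceptance band.  Every stochastic step takes an explicit seed; identical
configs and seeds reproduce identical outputs, which the pipeline manifest
records via input/output hashes.

## Known limitations

Registration, HU calibration, wavelet/LoG filtered features, 2-D feature
modes and resegmentation windows are out of scope.  The texture set's
exact 73-feature composition and the screening chain reconstruct printed
counts and named tests rather than a published itemization, and are
config-visible for that reason.  Reader AUCs from binary calls are
two-point ROC approximations.  The mesh smoothing trades sharp-edge
accuracy for smooth-surface accuracy, as quantified above.
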