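# Methods

## Problem

Multivariate lesion-symptom mapping (LSM) asks which locations of brain
damage account for a behavioral deficit across a patient cohort. This
package implements an SVR-based variant for dissociating phonological and
semantic verbal working memory (WM) after left-hemisphere stroke: two span
tasks measure the two WM capacities, a picture-word matching task measures
single-word input processing, and an RBF-kernel support-vector regression
relates the full lesion pattern to each WM score after the other score and
the nuisance covariates have been regressed out.

## Behavioral scoring

**Interpolated span.** Each span task administers increasing list lengths
(digit matching: 2-6 with 6, 8, 6, 8, 10 trials; category probe: 1-4 with
8, 8, 12, 16 trials) and stops at the first length scored below 75%. The
span is the list length at which accuracy crosses 75%, linearly
interpolated between the last length at or above threshold (accuracy
`a_lo`) and the first below (`a_hi`):

    span = L_lo + (L_hi - L_lo) * (a_lo - 0.75) / (a_lo - a_hi)

Edge rules: when even the shortest list is failed, a virtual length one
item below the task minimum is assumed at 100% accuracy (digits: length 1;
probe: length 0, keeping scores positive); when the longest list is passed,
a virtual length one above the maximum is assumed at 50% (chance for these
yes/no tasks). Perfect performance therefore scores 6.50 (digits) and 4.50
(probe). Accuracies are held as proportions internally; the interpolation
ratio is unit-invariant, so the percentage-point formula above gives
identical values. The threshold is a parameter (default 0.75, open
interval (0.5, 1)); curves that violate the administration rules (trailing
entries after a failed length, ending above threshold before the maximum)
are rejected rather than silently rescored.

**Signal detection.** Input processing is scored as d' = z(H) − z(F) per
foil condition (phonological, semantic), with the half-trial correction
for extreme proportions: observed rates of 0 or 1 are replaced by 1/(2N)
and 1 − 1/(2N). With 17 trials per category this puts the ceiling at
2·z(33/34) = 3.78, the maximum attainable score. The correction mode is a
parameter (`half_trial` default, `none` to refuse extreme rates). Both
foil conditions share the match trials, so the two d' scores share their
hit rate.

**Composite.** The two d' scores are standardized and summarized by the
first principal component of their 2x2 correlation matrix, which has the
closed form: eigenvalue 1 + r, explained-variance fraction (1 + r)/2, both
loadings sqrt((1 + r)/2), component scores (z1 + z2)/sqrt(2). The
component is signed so loadings are positive (higher composite = better
input processing). At r = 0.69 this gives 84.5% explained variance and
loadings of 0.92.

**Dependent variables.** Each WM score is residualized in one multiple
OLS regression on lesion size (voxel count of the unfiltered mask), the
input-processing composite, and the opposing WM score — a single
simultaneous regression, not a sequence — then min-max scaled to [0, 1].
Candidate demographic covariates can be screened by Pearson correlation
with Bonferroni correction (`screen_covariates`); only candidates
significant after correction would be added to the regression.

## Lesion design matrix

Binary masks on a common grid are stacked into a subjects x voxels matrix.
Voxels lesioned in fewer than `min_subjects` (default 5; a fraction is
interpreted as a proportion of the cohort) are dropped — with almost no
lesioned subjects a voxel's effect is statistically unidentifiable. Voxels
with identical lesion patterns across subjects are merged into *patches*;
the compression is lossless and deterministic (patches ordered by smallest
member voxel index). Patch multiplicities (voxel counts) enter the SVR
kernel as squared-distance weights,

    k(u, v) = exp(-gamma * sum_j m_j (u_j - v_j)^2),

so every kernel entry — and therefore every fit, CV error and permutation
statistic — is bit-for-bit what the full voxel matrix would give, at a
fraction of the cost. Lesion volumes are recorded before filtering and are
unaffected by it.

## SVR-LSM

**Model.** Epsilon-SVR (libsvm via scikit-learn, precomputed kernel) with
the weighted RBF kernel above, predicting the scaled score from the patch
pattern. Epsilon defaults to 0.1 (the conventional default of the libsvm
lineage); solver iterations are capped at 2e6 to bound pathological
grid corners (at these problem sizes libsvm converges far earlier).

**Hyperparameter selection.** Decade-stepped log grid over cost
[1e-2, 1e9] and gamma [1e-9, 1e3] (12 x 13 pairs by default,
configurable). For each pair the 5-fold cross-validated MSE (seeded,
shuffled folds, shared across the grid) is ranked against the same
statistic under `n_perm` score shuffles (one shared seeded set of shuffles
scores the whole grid, making the p-values comparable):
`perm_p = (1 + #{null <= real}) / (n_perm + 1)`. The pair with the lowest
perm_p wins; ties break on the real CV MSE, then smaller cost, then
smaller gamma. The winner's perm_p is reported as the model significance.
Caveat: this p-value is a selection minimum and is not re-validated
out-of-sample; it is reported as-is, as is conventional for this
procedure.

**Beta map and inference.** The per-patch statistic is the dual-coefficient
back-projection `beta_j = sum_i alpha_i X_ij` over support vectors — the
standard multivariate SVR-LSM sensitivity map; only the ranking of betas
matters for inference. (An analytic-gradient sensitivity map is available
as an alternative via `sensitivity_map`, not used by default.) The model
is refit on `n_perm` fresh shuffles of the scores (a flag allows reusing
the selection shuffles); each patch's p-value is the add-one lower-tail
rank of its observed beta in its own permutation null. A patch is
significant when p < alpha (default 0.05) AND its beta is negative —
damage is only expected to lower performance. No correction across patches
is applied (an FDR mode exists in the p-values' consumers' hands; the
default mirrors the uncorrected convention of the method). Failed
permutation fits are resampled and counted. P-values are discrete
multiples of 1/(n_perm+1); with strict `p < 0.05` and 199 permutations the
attainable level is 9/200 = 0.045, slightly conservative.

**Outputs.** Patch statistics are expanded to voxel maps (NaN outside
coverage), thresholded maps are summarized per atlas region (regions below
100 mm3 are flagged sub-threshold rather than dropped, sorted by volume),
and between-region damage-correlation / centroid-distance matrices are
available as collinearity diagnostics.

## Synthetic cohorts

No patient data ship with the package; a seeded generator produces
cohorts with the statistical structure the method assumes, so every stage
is exercised end to end.

- **Grid:** 24 x 24 x 18 voxels at 1 mm (configurable) — a desk-scale
  stand-in for one hemisphere. Lesion target volumes are drawn from the
  lognormal whose arithmetic moments match the clinical distribution
  (mean 14 098 mm3, SD 18 641 mm3; moment-matched mu = 9.05, sigma = 1.01),
  clipped to [135, 104 243] mm3, then multiplied by `volume_scale`
  (default 1/64) so the mean lesion occupies ~2% of the grid — the same
  fraction the clinical mean occupies of a hemisphere (equivalently, the
  grid behaves like a hemisphere sampled at 4 mm).
- **Lesions:** one connected blob per subject, grown by a priority flood
  (distance from a jittered seed center perturbed by seeded noise), giving
  compact but irregular 6-connected lesions. Seed centers come from a
  small set of blob centers emulating clustered vascular coverage. The
  cohort is resampled until each ground-truth region is lesioned in at
  least 5 subjects somewhere, so the coverage filter cannot erase the
  signal.
- **Truth regions:** two disjoint radius-3 spheres; damage in region A
  lowers the phonological latent, region B the semantic latent.
- **Behavior:** latent_k = baseline_k − effect_k·(damaged fraction of
  region k) − size_coef·z(log volume) + c·g + noise, with a shared factor
  g producing the between-score correlation. Defaults (baselines 5.4/2.5,
  effects 5.0/4.5 span units, size_coef 0.4, noise SD 0.6) were chosen to
  reproduce the clinical patient score distributions: phonological span
  ~4.9 ± 1.6, semantic span ~2.2 ± 1.4, cross-score r ~0.51, input d'
  correlation ~0.69. Latents map to *trial-level* data: per list length,
  correct counts are Binomial with accuracy 0.5 + 0.5·logistic(slope·
  (latent − length)) — the 75% crossing sits at the latent, so the scored
  span estimates it — honoring the stop rule; picture-word tallies use a
  shared hit rate from the mean input latent and foil-specific
  false-alarm rates placed so each condition's expected d' equals its
  latent.
- **Correlation calibration:** sampling noise attenuates correlations
  between *scored* variables below the latent ones, while shared match
  trials inflate the d' correlation. The shared-factor weight is therefore
  solved by a short fixed-point iteration: draw a cohort, measure the
  scored correlations (averaged over three replicate draws), scale the
  internal latent target by the ratio of desired to observed, re-solve,
  repeat up to three times. Targets that are infeasible at the configured
  noise level raise an error naming the bound.

What the generator does **not** emulate: vascular-territory anatomy,
spatially varying lesion frequency along real arterial distributions,
non-binary or mis-registered masks, behavioral missingness, and any
cognitive structure beyond the two-region + shared-factor model. Passing
recovery tests therefore demonstrate statistical correctness of the
pipeline under its own assumptions, not clinical validity.

## Validation strategy and known limits

- Scoring rules are pinned to their printed worked examples and ceilings
  (3.60; 6.50; 4.50; d' 3.78; composite 84.5%/0.92).
- Patch compression is verified lossless against direct voxel computation
  (kernels and expanded betas equal to 1e-10 on random matrices).
- Permutation p-values are checked two ways: against the exhaustive
  720-permutation null at n = 6, and by global-null calibration (100
  simulated null cohorts at n = 50, 199 permutations): the significant
  fraction stays within 2 Monte-Carlo SEs of alpha.
- Ground-truth recovery runs the full pipeline (trial tables -> scoring ->
  residualization -> mapping) on the default cohort over 5 seeds with a
  restricted 4 x 4 grid (cost 0.1-100, gamma 1e-4-1e-1) and 199
  permutations — sizes chosen to keep the suite at desk scale. Each
  score's significant map is compared with its own and the other score's
  truth region.
- **Spatial resolution limit:** blob lesions make damage at voxels just
  outside a truth region nearly collinear with damage inside it, so
  significant maps spill into a 1-2-voxel halo. Voxelwise false-positive
  rates computed against the exact sphere boundary hover near 0.03-0.05
  and can exceed 0.05 in individual seeds precisely when recovery is
  strongest. This is a property of lesion anatomy (no method can resolve
  features below the spatial autocorrelation scale of the damage), not of
  the inference, whose calibration is verified under the null.
- Degenerate inputs: constant dependent scores, empty coverage,
  rank-deficient covariate designs, zero-variance d' inputs and
  non-binary masks raise informative errors rather than propagating NaNs.

## Reproducibility

All randomness flows from one master seed through named CRC32-keyed
substreams (`lesion-sim`, `behavior-sim`, `cv-folds`, `param-perms`,
`inference-perms`), so each component is independently reproducible and
insensitive to the draw counts of the others. Identical configuration
yields bit-identical grid searches, inference results and output files.
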