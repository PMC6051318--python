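# Methods

`aphasiamap` implements a functionally-partitioned lesion-prediction framework
for chronic post-stroke aphasia. This note documents the models, the
synthetic-data generator, the numerical choices, and what the package's tests
do and do not establish about real data.

## The analysis model

The scientific claim the framework operationalises is that each patient's
aphasia profile reflects graded damage to a small number of primary
neurocognitive systems (phonology, semantics, speech quanta, ...), each with a
discrete lesion correlate. The pipeline therefore:

1. **Behavioural factorisation.** The n x T battery of test scores (T tests,
   mixed percentages and raw counts) is decomposed by PCA of the
   *correlation* matrix — the only defensible common scale for heterogeneous
   units. Components with eigenvalue strictly > 1.0 are retained (Kaiser
   criterion) and rotated by varimax with Kaiser row normalisation. Subject
   factor scores use the regression method, `Z R^{-1} Lambda`, with holdout
   subjects standardised by *training* means and SDs. Factor sign is fixed by
   making the highest-|loading| test of each factor load positively, and
   factors are ordered by post-rotation explained variance.

2. **Lesion-symptom mapping (VBCM).** Each factor score is regressed, voxel by
   voxel, on `[intercept, lesion status, lesion volume, age]`. Voxels must be
   lesioned in at least `min_coverage` patients and intact in at least
   `min_coverage` (default n/10). The t statistic of the lesion term is
   thresholded at one-tailed p < 0.005 in the deficit direction (lesion ->
   lower score; a two-tailed option exists), components are labelled under
   26-connectivity (configurable 6/18/26), and cluster-level family-wise error
   is controlled by the permutation null of the maximum cluster extent
   (Freedman–Lane residual permutation so the nuisance covariates are
   respected; a cluster-mass statistic is available behind a flag). Cluster
   p = (b + 1)/(n_perm + 1). Clusters with FWE p < 0.05 are merged into one
   binary mask per factor.

3. **Predictors.** Each patient's binary lesion yields percentage overlaps:
   `LV` (% of the left-hemisphere mask lesioned), `overlap_k` (% of functional
   cluster k lesioned) and `residual_LV` (% of the hemisphere *outside* the
   cluster union lesioned). The "residual hemisphere" reading of the residual
   lesion-load variable is this package's interpretation; a total-LV
   alternative can be obtained by supplying custom model specs.

4. **Cross-validated prediction.** Patients are split into k = 5 random folds
   (70 patients -> 14 per fold). Within every training set the PCA, the VBCM
   and the cluster masks are re-derived; per-test OLS models are fit on the
   training patients and applied to the holdout fold. Model fit is summarised
   by the adjusted R^2 of the full-cohort fit, predictive power by the mean
   per-fold Pearson correlation between predicted and observed holdout scores
   (a pooled-prediction correlation is reported as a secondary column since
   the two conventions differ slightly). Ten model variants are compared: the
   LV family ({LV} plus age / edu / onset / all) and the LV-PCA family
   ({residual_LV + cluster overlaps} plus the same demographics). Predictors
   are not standardised before OLS, so coefficients stay on natural scales.

5. **Inference.** Per model/test significance comes from a Monte-Carlo null
   (outcome permuted, default 10,000 iterations, p = (b+1)/(N+1)); model pairs
   are compared with two-sided Wilcoxon signed-rank tests on the 21 per-test
   metrics (exact null for n <= 25, normal approximation with continuity
   correction above; at n = 2 the two-sided p can never fall below 0.5).
   Poorly-predicted patients are flagged when their root residual sum of
   squares across tests exceeds mean + 2 SD.

6. **Classification.** Fluency status (binary logistic) and 7-way subtype
   (multinomial logistic) are predicted from the winning predictor set.
   Accuracy is in-sample, matching how such classifications are usually
   reported for a single cohort; the honest chance level is therefore the
   *permutation* mean (label-shuffle refits), which for imbalanced classes
   sits at or above the majority-class proportion. A k-fold cross-validated
   accuracy mode exists behind a flag for honest generalisation estimates.

### Cluster identity across folds

Clusters inherit the identity of the factor that generated them (factor 1 =
largest post-rotation variance, etc.); no spatial matching between folds is
attempted. If a training fold retains fewer factors than the target, or a
factor yields no surviving cluster, that factor's predictor falls back to the
residual-hemisphere region and the event is logged; exactly duplicated or
constant predictor columns are dropped before the OLS fit (also logged).

The pipeline also accepts *fixed* a-priori partitions (a dict of binary
masks), mirroring the common situation where the functional clusters come from
a prior study rather than being re-derived per fold.

## The synthetic cohort generator

No patient data are shipped beyond one printed demographic table, so every
statistical property is exercised on synthetic cohorts with known ground
truth.

* **Grid.** Default 40 x 48 x 40 voxels at 4 mm isotropic; most tests use a
  20 x 24 x 20 desk-scale grid. The hemisphere mask is a half-ellipsoid
  (~1,950 voxels at desk scale).
* **Lesions.** Single 6-connected blobs grown by randomised boundary
  accretion (accretion probability proportional to the squared count of
  already-lesioned neighbours), seeded in the central 60% of the hemisphere to
  mimic the concentration of middle-cerebral-artery infarcts. Lesion volume is
  log-normal as a fraction of the hemisphere (median 0.12, log-SD 1.0, clipped
  to [0.005, 0.7]), matching the order-of-magnitude spread of real chronic
  cohorts (lesions from a few hundred to tens of thousands of 2 mm voxels).
* **Functional regions.** K = 3 disjoint compact territories (phonology,
  semantics, speech quanta), each 12% of the hemisphere, grown with a strong
  compactness bias so they are near-spherical. The size was chosen so that the
  regions remain statistically resolvable at desk-scale grids: much smaller
  territories have surface-to-volume ratios near 1, and the unavoidable
  one-lesion-radius halo of correlated voxels around a region then swamps it.
* **Scores.** With d_ik the % damage to region k,
  `score_ti = clip(100 * sum_k lam_tk (1 - e d_ik/100) / sum_k lam_tk
  - a_t (age_i - 65) + eps, 0, 100)`, effect size e = 1, age coefficient
  a_t = 0.35 %/year, noise eps ~ N(0, 8) score units. The loading matrix has
  simple structure (each test loads 1.0 on one factor, 0.1 elsewhere). The
  linear clipped link is an artifact choice — the real mapping from damage to
  behaviour is unknown — kept linear so that recovery tests can invert it in
  closed form.
* **Demographics.** age ~ N(65, 12) years clipped [35, 90]; education
  ~ N(12, 2.2) years; onset log-normal with mean 56.6 / SD 50.17 months
  (moments taken from the packaged reference table), floored at 12 months.
* **Labels.** One 25%-damage threshold per factor maps the 2^3 damage cube
  onto seven BDAE-style labels (two cells share a label); fluency is the fixed
  partition {anomia, conduction, TSA} vs the rest. The rules are purely
  synthetic and carry no clinical validity; 25% was chosen as "substantial
  damage to a system" and yields roughly 70/30 fluent/non-fluent cohorts.

What the generator does **not** emulate: registration and segmentation error,
right-hemisphere or multifocal lesions, white-matter disconnection (a lesion
can only matter through the voxels it covers), non-Gaussian score noise,
floor/ceiling-induced skew beyond clipping, and any longitudinal recovery.
Passing tests therefore demonstrate that the *machinery* is correct and
calibrated, not that the effect sizes seen on synthetic cohorts transfer to
real patients — synthetic signal-to-noise is deliberately favourable, which is
also why the synthetic classification accuracies saturate near 100% (the
labels are deterministic functions of the predictors by construction).

## Numerical choices

* Varimax is run on Kaiser-row-normalised loadings by pairwise Jacobi planar
  rotations with the closed-form optimal angle; the criterion (sum over
  factors of the variance of squared loadings) is non-decreasing by
  construction and iteration stops below a 1e-10 gain or 1000 sweeps. A K = 1
  problem returns the identity.
* Rank-deficient correlation matrices (duplicated tests) are tolerated: score
  weights use the pseudo-inverse.
* The voxelwise GLM is computed by the Frisch–Waugh route: outcome and lesion
  columns are residualised against `[intercept, covariates]` once, then each
  voxel's t comes from the simple regression of residual on residual, which is
  algebraically identical to the full-design lesion-term t (verified against a
  per-voxel OLS oracle to 1e-8). Perfect fits (zero residual variance with a
  nonzero coefficient) are reported as signed infinity and flagged; a constant
  outcome gives t = 0; lesion columns collinear with the nuisance are dropped
  from the analysis mask.
* Permutation engines use `numpy.random.Generator` seeded from a single master
  seed; identical seeds give bit-identical outputs everywhere (cohorts, null
  distributions, fold plans).
* FWE permutation counts below 1/alpha - 1 trigger a warning because such a
  null cannot resolve the requested level.
* Logistic fits are Newton ML with bounded iterations; (quasi-)separation is
  detected and flagged rather than raised, with an L-BFGS fallback when Newton
  diverges (coefficient p-values are then unavailable and reported as NaN).
  The permutation-chance loop uses an unpenalised scikit-learn fit of the same
  likelihood for speed; a test pins it against explicit statsmodels refits.

## Problem sizes used by the test suite and acceptance script

FWE calibration uses 200 null replicates at n = 40 on the 20 x 24 x 20 grid
with 500 permutations; region recovery uses 20 cohorts x 3 factors at the same
scale; the model-family comparison uses 20 cohorts of 70 patients with 200 FWE
permutations per fold/factor; Monte-Carlo calibration uses 200 replicates of
200 iterations. These sizes keep the whole suite in a few minutes while
leaving the binomial bands around each calibration target tight enough to be
informative.

## Known limitations

* The permutation FWE correction assumes exchangeable outcomes under the
  null; covariate effects are handled by Freedman–Lane residualisation, which
  is approximate at small n.
* In-sample classification accuracy is optimistic by design (see above); use
  the cross-validated mode for generalisation claims.
* The max-extent cluster statistic favours large, smooth effects; focal
  effects smaller than the coverage threshold are invisible.
* On desk-scale grids a recovered cluster always carries a one-voxel halo of
  lesion-correlated neighbours, so Dice against the true region plateaus
  around 0.6–0.8 even for strong effects.
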