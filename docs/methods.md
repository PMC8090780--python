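# Methods

## The normative-modeling analysis

`normdev` implements a voxel-wise normative-modeling analysis of structural
gray-matter heterogeneity in case–control cohorts. The healthy-population
distribution of smoothed gray-matter volume is modeled per voxel as a
Gaussian process (GP) over age and sex; each individual is then scored by a
normative probability map (NPM) of Z-scores, one per voxel:

    y_v ~ GP(0, k_v) + eps_v,    eps_v ~ N(0, s2_v)
    Z_iv = (y_iv - yhat_v(x_i)) / sqrt(var_v(x_i) + s2_v)

with kernel `k(x, x') = v_c + v_l <x, x'> + v_f exp(-||x - x'||^2 / 2 l^2)`
on z-scored covariates `x = (age, sex)`. The denominator uses the full
predictive variance of an *observation* (GP posterior variance plus noise
variance), not just the posterior variance of the mean, because the Z-score
references an observed volume.

Healthy subjects are scored out-of-fold under 10-fold cross-validation
(random partition stratified by sex, seeded); patients are scored by the one
model trained on all healthy subjects. Downstream stages:

* **Extreme deviations** — per-tail thresholds |Z| > 1.96 / 2.6 / 3.1
  (per-tail p = .025 / .005 / .001, strict inequality) or per-subject
  Benjamini–Hochberg FDR at q = .05 on two-sided normal p-values; summarised
  per subject as the percentage of in-mask voxels in each tail, and by an
  extreme-value summary (mean of the top 1% of |Z|, `ceil(0.01 V)` values)
  to which a Gumbel distribution is fit across subjects by maximum
  likelihood.
* **Group inference** — pairwise Mann–Whitney U tests on the extreme scores
  (exact null when min(n) ≤ 8 and no ties, tie-corrected normal
  approximation otherwise), Bonferroni–Holm correction across the pairs
  within each metric, Pearson (optionally Spearman) correlations of scores
  with symptom covariates, pooled across the patient groups and within each
  group, and the prevalence ratio of group means of extreme-negative
  percentages.
* **Voxel-wise GLM** — cell-means OLS per voxel with directional group
  contrasts; inference by label permutation (Freedman–Lane residual
  permutation when nuisance regressors are present), with FWER control from
  the permutation distribution of the voxel-wise maximum of the same signed
  statistic. Corrected p ≥ uncorrected p by construction and the smallest
  achievable p is 1/(n_perm + 1). Two-sided questions are answered by a
  contrast and its reverse.
* **Overlap maps** — per group (optionally per sex), the proportion of
  subjects extreme at each voxel, with peak value and location (ties broken
  to the lowest flat index, all tied peaks reported).

## GP fitting: tied covariance, per-voxel noise

Every voxel shares the same covariate matrix, so the multi-output fit
factorises. By default the four covariance hyperparameters are optimised by
marginal likelihood (L-BFGS with analytic gradients, multi-restart, bounded
log-parameters) on a seeded random subsample of voxels (default 15) and
median-pooled in log space; the per-voxel noise variance is then optimised
exactly for all voxels at once through a single eigendecomposition of the
shared signal kernel (dense grid over log s2 with a parabolic refinement).
This is orders of magnitude faster than independent per-voxel optimisation
and is the statistically natural choice when all voxels see identical
covariates; full per-voxel optimisation of all five hyperparameters remains
available (`hyperparams="per-voxel"`). On Cholesky failure a jitter of
1e-6 × the maximum diagonal is added, escalating tenfold up to 1e-2 before
erroring.

Targets are z-scored per voxel by training statistics and predictions
de-standardized; covariates are z-scored by training statistics. Queries
outside the fitted age range warn (extrapolation is allowed; the reference
age span is 20–70 years). The forward-model slope reported per sex is the
linearized trajectory `(yhat(70, sex) - yhat(20, sex)) / 50` per voxel.

## The synthetic cohort generator

No clinical MRI data ship with the package; the generator emulates the
statistical structure the analysis assumes, and its defaults *are* the
reference study conditions used by the test suite and the acceptance script:

* **Cohort** — 400 healthy controls (HC), 116 bipolar-disorder (BP) and 94
  schizophrenia (SZ) subjects; group-specific age distributions (truncated
  normal on 20–70 years), sex ratios, and PANSS component scores (positive,
  negative, general; total = sum) with SZ means above BP means. PANSS and
  onset fields are missing for HC.
* **Voxel space** — 20×24×20 grid, ellipsoidal mask (~3,800 voxels), eight
  parcels (contiguous slabs) with age slopes from −0.004 to −0.001
  units/year, steepest in the two designated "frontal" parcels, which also
  carry a +0.02 sex offset for males.
* **Noise** — white Gaussian fields smoothed to FWHM 2 voxels (the analogue
  of 8 mm smoothing at 4 mm voxels) and rescaled so that every voxel's
  marginal sd is exactly `noise_sd` = 0.05. The rescaling uses the exact
  per-voxel variance of the separable linear filter (squared-kernel
  correlation), so Z-calibration checks are analytic, not empirical.
* **Patient effects** — two distinct mechanisms, mirroring the phenomenon
  the analysis is designed to expose. (1) A *diffuse group-shared deficit*
  in the vulnerable parcels (−0.022 units for SZ, −0.006 for BP; ~0.44 and
  ~0.12 noise-sd units): this is the robust group-level case–control effect
  that the permutation GLM detects. (2) *Idiosyncratic focal lesions*:
  per-subject Poisson counts (λ_SZ = 4, λ_BP = 1, λ_HC = 0) of spherical
  cosine-tapered blobs (radius 3 voxels, amplitude uniform in
  [−0.24, −0.14]) whose centers are drawn with 3× weight in the vulnerable
  parcels but are otherwise independent across subjects: these drive the
  individual extreme deviations and stay spatially sparse across subjects.

  The lesion and deficit amplitudes were calibrated once, from the Gaussian
  exceedance arithmetic and a Monte-Carlo check, so that under the default
  conditions (i) extreme-negative deviations at |Z| > 2.6 are roughly four
  times more prevalent in SZ than in HC, (ii) the HC>SZ contrast is
  FWER-significant essentially only inside the vulnerable parcels, and
  (iii) the peak SZ extreme-negative overlap stays near 10–13% — robust
  group effects, sparse individual overlap.
* **Symptoms** — PANSS components get a small lesion-burden slope
  (0.25 total points per lesion). With realistic PANSS group means the
  pooled patient correlation between extreme-negative percentage and PANSS
  total is dominated by the BP/SZ group separation and lands near 0.4; a
  pooled value as low as ~0.2 is not reachable jointly with the ~4×
  prevalence design and the instrument's group means, so the generator keeps
  the marginals realistic and reproduces the qualitative pattern instead:
  pooled correlation positive for the negative tail, near zero for the
  positive tail, and near zero within each patient group.

What the generator does **not** emulate: raw T1 images, segmentation,
scanner/site effects, non-Gaussian biological variability, and spatial
autocorrelation of the *signal* (only the noise is smoothed). Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Numerical choices and edge cases

* Thresholding uses strict inequalities; boundary ties are excluded.
* The extreme-value summary reads "trimmed mean of the top 1%" as the mean
  of the `ceil(0.01 V)` largest |Z|; an optional `trim_upper` fraction can
  additionally discard the very tip of that set. Gumbel is the default
  extreme-value family, with a generalized-EV alternative; an all-constant
  input is reported as a degenerate fit (scale 0) rather than an error.
* BH FDR runs within each subject's own map (the map is that subject's
  family of tests).
* Mann–Whitney with both groups constant and equal returns p = 1 (no
  evidence either way). Exact and normal-approximation p at n = 8 agree
  only to ~0.011 (the exact null is discrete); the tests assert the
  attainable bound.
* Zero-variance voxels: GLM t is set to 0 and flagged; evaluation
  correlations are reported missing.
* Holm's family defaults to the group pairs within a metric; configurable.
* The permutation GLM's group-only design omits age and sex on purpose —
  they are already absorbed by the normative model; a nuisance option
  (Freedman–Lane) is provided.
* Pipeline outputs use 0-based voxel coordinates, C-order flattening, an
  identity-scaled affine (voxel size on the diagonal), and a manifest with
  sha256 checksums; reruns with identical configuration and seeds are
  bit-reproducible.

## Problem sizes

The reference conditions (610 subjects × ~3,800 voxels, 10-fold CV,
1,000 permutations) keep a full analysis within a few minutes on one CPU;
they are the package's chosen study scale, with the grid and rates above
standing in for whole-brain VBM resolution. Error-control simulations in
the test suite use 5,000 null replicates for scalar tests and 500
replicates at reduced permutation counts for the permutation GLM.

## Known limitations

* Single-site model: no hierarchical or multi-site normative modeling.
* Gray matter only; no white-matter models, no cluster-extent or TFCE
  inference, no spatial statistics beyond the max-statistic correction.
* The GP kernel is a conventional normative-modeling choice; the tied
  hyperparameter default trades per-voxel kernel flexibility for speed and
  stability (per-voxel noise is always free).
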