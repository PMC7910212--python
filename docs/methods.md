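# Methods

This note documents the statistical models implemented in `endopls`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the package's numerical conventions and known limits.

## 1. Polygenic scoring

A subject's score for a trait is `score_i = Σ_j beta_j · d_ij` over the SNPs
with discovery p-value `p_j < 0.05`, where `d_ij ∈ [0, 2]` counts the effect
allele. Conventions:

* **Fixed single threshold.** No threshold scan is performed. Scanning
  thresholds against the phenotype selects the score most correlated with it
  and invalidates downstream brain–score correlations; a single nominal
  threshold avoids both the circularity and the extra multiplicity.
* **Allele alignment.** Where the summary-statistics effect allele is the
  dosage file's *other* allele, beta is negated; strand-ambiguous sites
  (A/T, C/G) and irreconcilable allele pairs are removed, with counts
  logged. PLINK `.raw`-style inputs name only the counted allele; alignment
  then reconciles through that allele alone.
* **Centring/standardization.** Scores are mean-centred and scaled to unit
  (population) SD before downstream use. Centring makes the score exactly
  invariant to which allele a file counts (a coding flip shifts every
  subject by the constant 2β); scaling is harmless because every downstream
  statistic is correlation-based.
* **Missing dosages** contribute zero to the sum (logged), the simplest
  auditable default; mean imputation is deliberately not silently applied.
* **Clumping** (greedy, index SNP by ascending p, removing neighbours
  within 250 kb at sample r² > 0.1, ties broken by (p, chrom, pos, id)) is
  available but **off by default**: the synthetic cohorts carry no linkage
  disequilibrium, and on real data the choice should be the user's.

## 2. Cohort preparation

* **BMI inclusion** keeps 18.5 ≤ BMI ≤ 50 with *strict* exclusion
  inequalities (BMI < 18.5 or > 50 removed; the boundary values are kept).
* **Two analysis samples.** Step 1 runs on all subjects with genetic and
  phenotype data; Steps 2–3 run on the subset that also has both imaging
  views, mirroring the usual attrition between questionnaire and scanner.
* **Covariates** — sex, imaging site (a factor with ≥ 4 levels, expanded to
  drop-first indicators), age, total intracranial volume, and eight genetic
  principal components — are removed from every block by OLS
  residualization before modelling. Residualization is idempotent and makes
  the correlation of two residualized variables equal their partial
  correlation given the covariates. The design matrix is checked for full
  column rank (collinear columns are named in the error) and internally
  column-scaled for conditioning, which leaves the projection unchanged.
  By default the PRS themselves are residualized too; `residualize_prs=False`
  restricts adjustment to phenotypes and imaging.
* **Standardization** uses the population-SD convention (divisor *n*),
  matching the permutation engine's internal normalization; any consistent
  convention gives identical correlations. Constant columns are dropped
  with a warning.
* Covariates are removed once, on the full sample, rather than inside each
  cross-validation fold. This matches the "adjust everything, then model"
  design and keeps fold scores comparable; the residualization step leaks
  only covariate means/slopes, not phenotype–brain structure.

## 3. Sparse partial least squares

One latent component linking the standardized explanatory block
`X (n × 4)` to the standardized, concatenated imaging block `Y (n × p)`:

```
maximize  u'(X'Y/n)v   s.t.  ‖u‖₂ ≤ 1,  ‖v‖₂ ≤ 1,  ‖v‖₁ ≤ c.
```

* `c = 1 + l1_frac·(√p − 1)` interpolates between one active voxel
  (`l1_frac = 0`) and the unconstrained leading singular pair
  (`l1_frac = 1`). The default `l1_frac = 0.18` was fixed by a pilot
  recovery study on the generator's default substrate (n = 600): it gave
  ≈ 0.99 sensitivity and ≈ 0.998 specificity for the planted support,
  whereas 0.12 under-selected and 0.25 over-selected.
* Alternating updates `u ← Mv/‖Mv‖`, `v ← S(M'u, λ)/‖·‖₂` with
  `M = X'Y/n`; λ is found by bisection (resolved to 1e-10 relative) so the
  L1 constraint binds. Iteration stops when the largest weight change falls
  below `tol = 1e-6` (cap 500 iterations; non-convergence warns and returns
  the flagged trace). The objective is monotone non-decreasing across
  iterations up to tolerance.
* **Sign convention:** the global sign of (u, v) is arbitrary; the BMI
  element of u is made non-negative.
* **Two-block realization.** The two imaging views are standardized
  per-voxel, scaled to equal total variance (each divided by √p_view) and
  concatenated, so neither modality dominates the L1 budget; sparsity is
  applied to the imaging side only, since all four explanatory variables
  are to be interpreted. A single component is fitted — the model targets
  one shared substrate, not a deflation sequence.
* **Stability selection:** the penalized fit is repeated on 100 random
  80% subsamples (without replacement); a voxel's selection frequency is
  the fraction of fits with a nonzero weight, and voxels at frequency
  ≥ 0.8 form the stable support. The final weights are the unpenalized
  rank-one (SVD) refit restricted to that support; the per-subject
  endophenotype score is `Y·v` from this refit.
* **Cross-validated association:** within each of 5 folds the full
  stability-selection-plus-refit procedure is retrained and held-out
  subjects are scored, so every subject receives exactly one out-of-sample
  score; each explanatory variable's Pearson correlation with the pooled
  score is tested by one-sided permutation (add-one rule,
  `p = (1 + #{r* ≥ r})/(1 + B)`) and Holm-adjusted over the four-variable
  family. Permutations shuffle the explanatory variable against the fixed
  out-of-sample scores; refitting the entire sPLS per permutation would
  test the same null at vastly higher cost and is intentionally not the
  default.
* **Cluster reporting:** stable weights are split by sign and labelled by
  26-connectivity per modality; each cluster reports size, sign, peak
  |weight| voxel, centroid and mean weight.

## 4. Inference

* **Permutation tests** are one-sided (positive association), consistent
  with a method that only identifies positive weighted associations; the
  smallest attainable p is `1/(B+1)`.
* **Holm–Bonferroni**: step-down, `adj_(i) = max_k≤i (m−k+1)p_(k)` capped at
  1, returned in input order. The Step-1 family is the four reported
  correlation tests; the Step-2 family is the four variable–endophenotype
  tests. Family membership is an explicit argument.
* **Steiger's test** (non-overlapping dependent correlations): both
  correlations are Fisher-transformed and compared with
  `z = (z₁ − z₂)·√((n−3)/(2 − 2s̄))`, where s̄ is the Pearson–Filon
  covariance of the two z's evaluated with the *pooled back-transformed*
  correlation substituted for both compared entries (Steiger's Z̄₂*
  variant, the recommended form for this case). With all four
  cross-correlations zero it reduces exactly to the independent two-sample
  Fisher-z comparison; at n = 874 its Monte-Carlo size at α = 0.05 is
  within (0.044, 0.056). The overlapping (shared-variable) case is a
  deliberate stub.

## 5. Mediation

For each pathway (x = a PRS, m = endophenotype score, y = a phenotype):

```
m ~ 1 + x + C        →  a
y ~ 1 + x + m + C    →  b, c′
```

with unstandardized coefficients and the same covariates C in both
regressions. The indirect effect is `ab = a·b`, which in linear OLS equals
`c − c′` exactly (verified to 1e-10). Inference is a subject-level
nonparametric bootstrap (default 10,000 draws, internally vectorized over
batched normal-equation solves — identical to per-resample refits to 1e-8)
with **bias-corrected** percentile intervals:
`z₀ = Φ⁻¹((#{ab* < ab} + ½#{ab* = ab})/B)` and endpoints at the bootstrap
quantiles `Φ(2z₀ + z_{α/2})`, `Φ(2z₀ + z_{1−α/2})`. BC rather than BCa: no
acceleration constant is estimated. Both 90% and 95% intervals are always
reported. A BC interval can, in pathological z₀ cases, fail to contain the
point estimate; this is flagged, never forced. A fully degenerate bootstrap
(all ab* equal) reports the point mass as its own interval. The bootstrap
does not stratify by site; site enters as a covariate instead.

## 6. The synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
with complete ground truth:

* **Genotypes**: independent binomial(2, maf) dosages, maf ~ U(0.05, 0.5),
  1,000 SNPs by default. Two traits receive true effects on a shared causal
  set (30 SNPs, same sign and size in both traits) plus 30 trait-specific
  SNPs each; the shared-set effect size is solved in closed form so the
  *population* correlation of the two true genetic scores equals the
  configured PRS–PRS target exactly.
* **Summary statistics**: reported beta = true beta + noise with
  SD = 1/√(N·2·maf·(1−maf)) at the discovery sample sizes N = 55,374
  (ADHD-like, cases+controls) and N = 339,224 (BMI-like); p-values from the
  Wald statistic. About 30% of SNPs are reported on the opposite allele to
  exercise alignment. At these N the p < 0.05 score reconstructs the
  planted score at r > 0.9, so the full summary-stats route only mildly
  attenuates the planted correlations.
* **Latent substrate**: `L = a₁·zPRS_A + a₂·zPRS_B + ε`, unit variance,
  with default paths a = (0.15, 0.15) and substrate→phenotype effects
  b = (0.15, 0.20). These defaults were chosen (by a pilot power check) so
  that the four planted indirect effects are comfortably detectable at the
  default cohort size — slightly stronger than the associations a real
  cohort of this size would show, which is the right regime for recovery
  tests.
* **Phenotypes**: `pheno = c₁·zA + c₂·zB + b·L + γ'f + s·U + σ·ε`, where f
  are unit-variance covariate factors (sex, site, age, TIV, PC1), U is a
  shared non-genetic confounder, and the direct paths c and the confounder
  product s₁s₂ are solved analytically so the population 4×4 correlation
  matrix of (PRS_A, PRS_B, impulsivity, BMI) equals `target_corr`
  **exactly** (infeasible configurations raise). The two cells not pinned
  by the calibration targets default to 0.05, chosen to keep the matrix
  positive definite. Phenotypes are then put on familiar scales
  (impulsivity ≈ 62 ± 9 questionnaire points, BMI ≈ 24 ± 3 kg/m²), which
  leaves all correlations unchanged.
* **Imaging views**: `Y = L·m' + covariate leakage + smooth noise`, one
  12×12×12 grid per view. The loading map m has two well-separated
  spherical clusters per view (radius 2 voxels, Gaussian radial taper with
  a unique peak), all-negative for the grey-matter view and all-positive
  for the reward-task view. Noise is white noise convolved with an
  isotropic Gaussian kernel (FWHM 2 voxels) and rescaled to unit variance,
  mimicking smoothed maps so that cluster reporting is exercised;
  covariates leak into voxels through smooth random maps so that
  residualization is consequential.
* The four generative indirect effects are parameterized by the path
  vectors (a₁, a₂) and (b₁, b₂) rather than configured directly — four
  arbitrary products are not jointly realizable by one substrate, since
  a₁b₁·a₂b₂ = a₁b₂·a₂b₁ must hold; the products are exposed as a derived
  property, and `SyntheticTruth.implied_mediation` returns the exact
  population single-exposure (a, b, ab, c′) for any pathway from the
  model-implied covariance matrix.

**What passing tests do and do not show.** The generator has no linkage
disequilibrium, no genotyping error or imputation uncertainty, Gaussian
phenotype tails, site effects that are mean shifts only, and a substrate
that loads linearly and homogeneously. Recovery and calibration results on
these cohorts validate the *machinery* (estimators, resampling, error
control) — they do not certify performance on real imaging-genetic data,
where LD, heavy tails, scanner batch structure and weaker effects all bite.

## 7. Reproducibility and problem sizes

One global seed expands into fixed, named per-stage streams (genotypes,
summary stats, cohort, imaging, sPLS resampling, permutations, bootstrap),
so identical configurations are bitwise-reproducible and stages can be
re-run in isolation; every run directory carries a manifest with the seed
and a configuration hash. The test suite exercises the heavy simulations at
deliberately desk-scale sizes (e.g. support recovery over 20 seeds at
n = 600, bootstrap coverage at n = 300 with B = 2,000 over 1,000
replicates, family-wise error control over 100 null replicates at n = 250),
chosen to keep Monte-Carlo error well inside each asserted band while the
whole suite stays in the minutes range. `scripts/acceptance.py` runs the
complete pipeline at the full default scale (n = 874, 9,999 permutations,
10,000 bootstrap draws).

## 8. Known limitations

* Single latent component; no deflation sequence for further substrates.
* No anatomical labelling of clusters (coordinates only).
* Stability selection controls selection *stability under resampling* of
  one dataset; a noise voxel strongly correlated with the explanatory
  block in that dataset can be stably selected — the cross-validated
  permutation test, not the selection frequency, carries the error control.
* The mediator in Step 3 is the estimated endophenotype score, not the
  latent substrate; measurement error attenuates b (and ab) relative to
  the generative values, as in any real factor-score mediation.
* The overlapping-correlations Steiger case and BCa intervals are out of
  scope; causal-inference sensitivity analyses for mediation are not
  provided.
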