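# Methods

## Model and procedure

The package implements two-block Partial Least Squares Correlation
(PLSC). Given a behavioral block `Y` (n × q) and a brain block `X`
(n × p) on the same subjects, the analysis extracts paired latent
components that maximize cross-block covariance: the SVD of the
behavior-by-brain Pearson correlation matrix `R = Yzᵀ Xz / (n − 1)`
yields behavioral saliences `U`, brain saliences `V` and singular values
`s`. Component k's explained covariance is `100 · s_k² / Σ s²` with the
denominator over **all** `min(p, q)` singular values, so percentages do
not depend on how many components are retained. Latent scores are the
block projections; the per-component latent Pearson correlation is the
effect size reported alongside the permutation p-value.

Assumptions: linear brain-behavior coupling; confound effects
(age, sex, handedness) are additive and linear; subjects are
exchangeable under the null of no cross-block association; columns have
nonzero variance (constant columns are a hard error rather than a
silent drop).

## Preprocessing order

Scores are first oriented so higher = better (lower-is-better columns
negated; the flag set is an input, not inferred). Each block column is
then residualized against intercept + age + sex + handedness and finally
z-scored with the n−1 denominator. Residualizing **before** the final
z-scoring was chosen because it guarantees both the exact-Pearson
interpretation of `R` and unit-variance columns; the phrase "z-score and
residual-correct" is ambiguous in common usage, so the alternative order
(z-score, residualize, re-scale) is available via
`prepare_blocks(..., order="zscore_then_residualize")` and recorded in
the output metadata either way. The two orders differ only in column
scaling during the intermediate step and give identical prepared blocks
whenever the final re-scaling is applied.

Sex and handedness are consumed as numeric codes exactly as provided; no
internal recoding is attempted.

## Resampling inference

**Permutation test.** Rows of `Yz` are permuted against a fixed `Xz`
(equivalent by symmetry to permuting `X`), which breaks cross-block
association while preserving within-block covariance. Per permutation
the SVD is recomputed; by default the permuted singular structure is
Procrustes-rotated onto the original saliences (rotation from the SVD of
`U_obsᵀ U_perm`, applied to `V_perm diag(s_perm)`; the rotated null
singular value is the column norm), which stabilizes component identity
against axis rotation and reordering under permutation. P-values use the
add-one rule and therefore lie in `[1/(n_perm+1), 1]`. Residualization
is done once on the full sample; resampling operates on the prepared
blocks (re-residualizing within each resample, Freedman–Lane style, is
out of scope).

**Bootstrap stability.** Subjects are resampled with replacement; blocks
are re-standardized within each resample; each resample's saliences are
aligned to the original solution — by default a per-component sign flip
chosen by the dot product with the original saliences (Procrustes
alignment is available and advisable when components are close in
singular value). A variable's bootstrap ratio is `Z = bootstrap mean /
bootstrap SD` (the alternative numerator, the original salience, is a
config option); significance is `|Z| ≥ 3` by default. `|Z| ≥ 3`
corresponds to a one-tailed standard-normal tail of 0.0013 (two-tailed
0.0027); the looser conventional cutoffs 2 and 2.57 (two-tailed 0.01)
are exposed through the same threshold parameter, and
`normal_tail_probability` reports both tail conventions explicitly since
the two are easily conflated in applied reports. Degenerate resamples
(any constant column) are redrawn and counted.

**RNG discipline.** One master seed; the permutation and bootstrap
draws come from independent child streams (`[seed, 1]` and `[seed, 2]`),
so changing `n_perm` never alters bootstrap draws.

## ROI extraction

All volumes are assumed pre-registered to one grid (registration is
upstream, out of scope); shape equality is the only geometric check. A
probabilistic atlas is binarized by assigning each voxel to its most
probable region among those at or above the threshold (default 0.5),
ties to the lowest region index. Label sources are merged by precedence
(default: subcortical > cerebellar > cortical), with per-source
exclusion lists applied first — this encodes the usual convention of
dropping hippocampal parcels from a cortical parcellation in favor of a
subcortical atlas's hippocampus. Output labels are re-indexed
consecutively with source-qualified names. Parcel means over an empty
parcel are a hard error by default (`emit-missing` optionally records
NaN), because a silently absent ROI would corrupt the downstream block.

## Synthetic data

`generate_two_block` plants K rank-one cross-block components: latent
scores orthogonalized by QR (so planted components are identifiable),
unit-norm sparse saliences with disjoint supports, additive confound
contamination, i.i.d. Gaussian noise, and a minority "DR" subgroup with
mean shifts on designated behavioral columns. A target latent
correlation ρ maps to latent strength `λ = σ √(ρ/(1−ρ))`; recovery
difficulty at fixed ρ is invariant to the noise SD, since per-column
z-scoring removes the overall scale.

Defaults mirror the emulated cohort: n = 134, q = 36 measures, p = 397
ROIs, one component at ρ = 0.5, subgroup fraction 25/134 (≈19 %) with a
−0.8 SD shift on four behavioral columns, ages uniform on 18–47, sex
Bernoulli(92/134), handedness a clipped normal. The cosmetic confound
distributions are configurable and do not affect the inference tests.

What the generator does **not** emulate: spatially or temporally
correlated fMRI noise, non-Gaussian score distributions, missingness
mechanisms, site effects. Passing tests therefore demonstrate
correctness of the algorithms and calibration under exchangeable
Gaussian conditions, not robustness to realistic fMRI artifacts.

## Numerical choices

- SVD sign convention: each component's largest-|u| behavioral salience
  is made positive (SVD signs are arbitrary; this fixes them
  deterministically across platforms). Near-tied singular values trigger
  a logged warning since saliences are not unique under ties.
- Correlations use the n−1 denominator throughout, so `R` holds exact
  Pearson values; the n-normalized variant would only rescale all
  singular values by (n−1)/n and leave p-values, Z ratios and explained
  percentages unchanged.
- Stratified subsampling uses largest-remainder allocation (floor plus
  distribution of the remainder by fractional part, ties broken by group
  name), which preserves group proportions exactly in expectation and
  sums exactly to the target n.
- Residualization uses a least-squares projection (`lstsq`); a
  rank-deficient confound design is an error, not a silent pseudo-inverse.

## Known limitations and observed behavior

- In the p ≫ n regime (p = 397 ROIs, n = 134) the in-sample latent
  correlation is strongly optimistic (≈0.9 observed for a planted 0.5)
  and variable-level bootstrap ratios rarely reach |Z| ≥ 3 at moderate
  planted strength; both are properties of the method at this
  dimensionality, not of the implementation.
- Salience recovery at n = 134, p = 40, q = 36 and planted latent
  correlation 0.5 attains a median |cosine| of ≈0.74 against the planted
  direction: with λ²/(λ²+σ²) = 0.5 the planted part of `R` has Frobenius
  norm ≈0.9 while the sampling-noise singular-value edge of a 36×40
  cross-correlation at n = 134 is ≈1.07, so the signal sits at the noise
  edge. The estimate agrees with scikit-learn's `PLSSVD` to machine
  precision on identical data (a test enforces this); reaching ≈0.9
  recovery requires a planted latent correlation near 0.7. Detection
  (permutation p < 0.05) is much easier than estimation here: power is
  ≈0.9 at the same conditions.
- Only two-block PLSC is implemented: no PLS regression, sparse/penalized
  variants, CCA, multi-group PLSC, or FDR-style multiplicity correction
  beyond the |Z| threshold.

## Problem sizes used in the checks

The calibration check uses 500 null datasets (n = 50, p = 10, q = 8) at
200 permutations; the recovery simulation 50 replicates (n = 134,
p = 40, q = 36) at 500 permutations; the study-scale demonstration run
n = 134, q = 36, p = 397 with the full 1000 permutations and 500
bootstrap samples. These sizes give Monte-Carlo standard errors small
enough for the stated acceptance bands while keeping a full run in tens
of seconds.
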