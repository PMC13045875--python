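# Methods

## The biometric model

The unit of analysis is one regional mean of one DTI metric per subject,
for a cohort of MZ and DZ twin pairs. After removing age and sex effects,
the standardized trait variance is decomposed into additive genetic (A),
shared-environment (C) *or* dominance genetic (D), and unique-environment
(E, which absorbs measurement error) fractions. Model-implied within-pair
correlations follow the standard biometric algebra: MZ co-twins share A,
C and D fully; DZ co-twins share half of A, all of C, and a quarter of D:

```
ACE:  r_MZ = A + C        r_DZ = A/2 + C
ADE:  r_MZ = A + D        r_DZ = A/2 + D/4
```

Assumptions inherited from the classical design: equal environments across
zygosity groups, no assortative mating, no gene–environment interaction or
correlation, and (for the correlation-input likelihood) bivariate normality
of the adjusted trait within pairs. C and D cannot be estimated jointly
from twins reared together; the fitted model is chosen per region by the
observed pattern — **ADE iff `r_DZ < r_MZ/2`**, ties to ACE (preferring the
conventional C interpretation). Only the fully parameterized three-
component models are fitted; no AE/CE/E sub-model reduction is performed,
so small, non-significant components are retained as point estimates, and
no standard errors or confidence intervals are attached.

### Estimation

Input per region/metric is `(r_MZ, n_MZ, r_DZ, n_DZ)`. The fit maximizes
the normal-theory (Wishart-type) log-likelihood of the two observed 2×2
correlation matrices with unit diagonals,

```
-2 logL = Σ_g (n_g − 1) [ log(1 − ρ_g²) + 2 (1 − ρ_g r_g) / (1 − ρ_g²) ]
```

over the two free components, with bounds `A, C, D ≥ 0` and
`A + C + D + E = 1`, `E ≥ 0.001` (E contains measurement error and cannot
vanish). Optimization is SLSQP (`ftol = 1e-14`) from five deterministic
starts, one of which is the feasibility-clipped method-of-moments
(Falconer) point; the best likelihood wins, ties resolving to the smallest
A. Because the models are exactly identified, an interior optimum
reproduces the observed correlations exactly and equals the Falconer
closed form (`A = 2(r_MZ − r_DZ)`, `C = 2r_DZ − r_MZ`, `E = 1 − r_MZ`
under ACE; `A = 4r_DZ − r_MZ`, `D = 2r_MZ − 4r_DZ` under ADE) — the test
suite checks this equivalence to 1e-6 on random interior points. When the
moment solution has a negative component the ML fit pins it at the bound
(e.g. `r_MZ = −0.02, r_DZ = 0.07` gives A = 0 and a small common C that is
the inverse-variance-weighted compromise between the two groups).
Heritability is reported as G = A (ACE) or G = A + D (ADE).

### Twin correlations and adjustment

Values are residualized on age (years, unscaled) and sex (single male
indicator) with one pooled OLS fit per region/metric — pooling over
zygosity keeps a common covariate model, and opposite-sex DZ pairs are
retained because sex is regressed out first. The twin correlation is the
double-entry Pearson correlation (each complete pair enters in both
orderings), which is invariant to arbitrary within-pair labelling and
equals the ANOVA intraclass correlation of the stacked data; pairs with a
missing member value are dropped pairwise, and fewer than three complete
pairs yields no estimate. MZ and DZ correlations are compared with a
one-sided Fisher z test, `z = (atanh r_MZ − atanh r_DZ) / √(1/(n_MZ−3) +
1/(n_DZ−3))`. The report table rounds correlations/components to 2
decimals and p-values to 4, using decimal half-up rounding (numpy's
banker's rounding would turn a mean of exactly 0.705 into 0.70).

## Regional extraction

`AD = L1`, `MD = (L1+L2+L3)/3`, `RD = (L2+L3)/2`, and
`FA = √(3/2)·√Σ(Lᵢ−MD)² / √ΣLᵢ²` with FA = 0 at all-zero voxels. Small
negative eigenvalues are clamped to zero with a warning; an ordering
violation (`L1 ≥ L2 ≥ L3`) is an error.

Extraction assumes the skeletonised 4D maps and the integer atlas share a
voxel grid (no resampling is implemented — TBSS output and the JHU
ICBM-DTI-81 atlas live on the same 1 mm standard grid). Per region and
subject the mean is taken over voxels carrying the region's label whose
value is *exactly* 0.0-free: literal zeros mark off-skeleton voxels, so an
epsilon band would be wrong. Voxels are weighted uniformly (no skeleton-FA
weighting). A region with no qualifying voxels for a subject produces a
missing cell, which propagates (pairwise deletion downstream) and is never
imputed. Six posterior-fossa regions with poor skeleton representation
(MCP, PCT, bilateral ML and ICP) are excluded by default, leaving 42
analysis regions.

## Harmonization

Scanner effects are removed at the regional level with parametric
empirical-Bayes location/scale harmonization (ComBat), fitted per metric
across the region features, with age and sex as preserved covariates. The
implementation follows the canonical parametric algorithm: covariate-aware
standardization (pooled variance with an n divisor, per-batch variances
with n−1), moment-matched normal/inverse-gamma priors, and iterated
conditional posterior-mean updates until the maximum relative change falls
below 1e-4 (cap 100 iterations). Missing cells are excluded feature-wise
from estimation and passed through unchanged. A test verifies agreement
with the standard R implementation to better than 1e-6 on a shared
fixture. Harmonization refuses to run on a single batch (it would be a
no-op) and on designs where batch is collinear with a covariate. Note that
EB shrinkage makes the operator only *nearly* idempotent: refitting on
harmonized data removes a small residue (≲1% of the first-pass change when
the batch effect is substantial).

## Synthetic cohort generator

The generator emulates the study conditions this pipeline targets: 33 MZ
and 48 DZ pairs by default, ages shared within a pair and uniform on 9–32
years, DZ pairs opposite-sex with probability 10/48, two scanner sites
with a 47:81 / 34:81 split, and an exclusion cascade (psychiatric →
missing MRI → low-quality DTI) applied sequentially to randomly chosen
pairs. Traits are built from latent standard-normal factors scaled by
√A, √C, √D, √E; DZ additive latents are `√½·shared + √½·unique` and
dominance latents `√¼·shared + √¾·unique`, which reproduces the biometric
covariance algebra exactly (verified empirically at 10⁴ pairs). Covariate
effects are linear (defaults: 0.02 trait-SD per year of age, 0.10 trait-SD
male offset) and scanner effects are additive + multiplicative on the
trait deviation — precisely the location/scale form ComBat models.
Metric scales are physiologically plausible (FA ≈ 0.50 ± 0.06, clipped to
[0,1]; MD/AD/RD around 0.8/1.2/0.65 ×10⁻³ mm²/s); normality of regional
values is assumed, as the twin model requires.

What the generator does *not* emulate: raw diffusion-weighted images,
registration or skeleton-projection error, spatially correlated voxel
noise, region-to-region correlation within subject, age-dependent
heritability, or sex-limitation effects. Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to their violation in real MRI data.

Skeleton-volume fixtures place each region as a run of voxels in a zero
background (so "outside skeleton" voxels are exact zeros) and write the
subject's regional value, plus optional i.i.d. Gaussian voxel noise, into
the labelled voxels.

## Problem sizes and numerical choices

Simulation-based tests use 200-pair cohorts for harmonization properties,
10⁴ pairs per zygosity for covariance-structure checks (tolerance 0.02–
0.03), and 2,000 pairs per zygosity across 20 seeds for full-pipeline
parameter recovery (mean absolute component error < 0.05); these sizes
give sampling error comfortably below the asserted tolerances while
keeping the suite fast. All randomness flows through
`numpy.random.default_rng` seeded from the configuration, and pipeline
runs are bit-reproducible (the manifest records SHA-256 hashes of every
artifact).

## Known limitations

- Correlation-matrix likelihood, not raw-data SEM: no means model, no
  saturated-model assumption checks, no confidence intervals.
- Published tables print rounded correlations; fits from printed inputs
  can differ by ~0.01–0.02 in the A/D split (their sum G is stable) from
  fits on unrounded data, which is expected and not corrected for.
- The exact test behind published MZ-vs-DZ p-values in such tables is
  often unstated; the Fisher z comparison reproduces their magnitude but
  not necessarily the final digit.
- Per-metric harmonization treats metrics independently; joint multi-
  metric ComBat-GAM-style variants are out of scope, as are non-parametric
  priors and voxelwise harmonization.
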