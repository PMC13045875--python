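# twindti

Twin-study heritability analysis of white-matter diffusion-tensor (DTI)
metrics: regional extraction from TBSS skeletons, ComBat scanner
harmonization, age/sex-adjusted MZ/DZ twin correlations, and constrained
maximum-likelihood ACE/ADE variance decomposition — plus a synthetic
twin-cohort generator so the whole pipeline is testable without MRI data.

## The problem

Classical twin designs separate genetic from environmental influence on a
trait by contrasting monozygotic (MZ) twins, who share all segregating
genetic variants, with dizygotic (DZ) twins, who share on average half of
the additive and a quarter of the dominance genetic variance. Applied to
regional DTI metrics (FA, MD, AD, RD averaged over JHU ICBM-DTI-81 atlas
regions on a TBSS skeleton), this yields per-region estimates of
heritability of white-matter microstructure.

The standardized trait variance is decomposed as A + C + E or A + D + E
(shared environment C and dominance D are confounded in twins reared
together, so only one is fitted at a time). The model-implied within-pair
correlations are

```
ACE:  r_MZ = A + C        r_DZ = A/2 + C
ADE:  r_MZ = A + D        r_DZ = A/2 + D/4
```

ADE is selected when `r_DZ < r_MZ / 2`, otherwise ACE. Components are
estimated by maximizing the normal-theory likelihood of the two observed
2×2 within-pair correlation matrices (group weights `n−1`), subject to
non-negativity; the closed-form Falconer estimates
(`A = 2(r_MZ − r_DZ)`, `C = 2 r_DZ − r_MZ`, `E = 1 − r_MZ` under ACE)
serve as an independent oracle, and coincide with the ML fit whenever the
solution is interior. Reported heritability G is A (narrow-sense, ACE) or
A + D (broad-sense, ADE).

Upstream of the twin model the package provides: scalar-map computation
from tensor eigenvalues (`AD = L1`, `MD = (L1+L2+L3)/3`, `RD = (L2+L3)/2`,
FA from the normalized eigenvalue dispersion), atlas-based regional means
that exclude exactly-zero (off-skeleton) voxels, parametric empirical-Bayes
ComBat harmonization preserving age and sex, and double-entry Pearson twin
correlations with a one-sided Fisher z comparison.

## Worked example

The package bundles a reference table of regional twin correlations from a
published two-site twin cohort (33 MZ / 48 DZ pairs, 42 regions × 4
metrics). Running only the biometric stage on it:

```bash
python - <<'PY'
import pandas as pd
from twindti.datasets import load_reference_correlations, REFERENCE_N_MZ, REFERENCE_N_DZ
ref = load_reference_correlations()
ref[["region","metric","r_mz","r_dz","p"]].assign(
    n_mz=REFERENCE_N_MZ, n_dz=REFERENCE_N_DZ
).to_csv("ref_corr.csv", index=False)
PY
twindti run --mode from_correlations --correlations ref_corr.csv --out-dir demo
```

prints (abridged):

```
Twin correlation summary (mean [min, max] across regions)
  FA: MZ 0.71 [-0.02, 0.89]  DZ 0.49 [0.07, 0.66]
  MD: MZ 0.58 [0.10, 0.86]  DZ 0.37 [0.01, 0.57]
  AD: MZ 0.56 [0.17, 0.85]  DZ 0.34 [0.02, 0.58]
  RD: MZ 0.65 [0.24, 0.91]  DZ 0.42 [0.04, 0.59]
Regions with r_DZ > r_MZ (inverse pattern):
  FA: CST_R, SCP_R, CgC_R
  ...
Regions with G <= 0.05 (negligible genetic contribution):
  FA: CST_R (G=0.00), SCP_R (G=0.00), EC_R (G=0.04), CgC_R (G=0.00)
  ...
```

MZ correlations exceed DZ correlations in most regions (substantial
heritability — e.g. splenium FA: `r_MZ=0.89, r_DZ=0.54` → ACE with
A=0.70, C=0.19, E=0.11), while a few regions show no detectable genetic
contribution (right corticospinal-tract FA: `r_MZ=−0.02, r_DZ=0.07` → A
pinned at 0, E=0.97). The per-region fits land in `demo/report.csv`; a
manifest with content hashes makes reruns auditable.

A fully synthetic run (`twindti run --mode synthetic --seed 1 ...`)
generates a cohort with known components, harmonizes, adjusts, correlates
and fits — useful for power exploration and for validating the estimator
against ground truth.

## Layout

| module | contents |
| --- | --- |
| `twindti.cohort` | synthetic rosters, regional values with ACE/ADE covariance, skeleton-volume fixtures |
| `twindti.regional` | tensor scalar maps, atlas extraction, region exclusions |
| `twindti.combat` | parametric empirical-Bayes batch harmonization |
| `twindti.twinstats` | age/sex adjustment, double-entry correlations, Fisher z, demographics |
| `twindti.biometric` | ACE/ADE model selection, Falconer oracle, constrained ML fit |
| `twindti.pipeline` / `twindti.cli` | orchestration, report rendering, `twindti` console entry |

See `docs/methods.md` for model assumptions, parameter choices and known
limitations.
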