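# pardti

Free-water-corrected (dual-compartment) DTI analysis of neurodegeneration,
with tensor-based morphometry and voxel-wise permutation inference —
plus a synthetic multi-shell DWI cohort generator with known ground truth.

## Who this is for

Neuroimaging methods researchers who want a tested, self-contained
implementation of the dual-compartment DTI group-analysis pipeline used to
study atrophic disease (e.g. cerebellar ataxias), where conventional DTI
metrics are confounded by CSF-like free water: atrophy inflates the
apparent mean diffusivity (MD) and deflates fractional anisotropy (FA)
even when the remaining tissue is intact.

## The model

Each voxel's multi-shell diffusion signal is a two-compartment
biexponential,

    S_i = S0 * ( f_par * exp(-b_i : D_par) + (1 - f_par) * exp(-3e-3 * b_i) ),

with a parenchymal tensor compartment `D_par` (eigenvalues constrained to
[0, 3e-3] mm^2/s) and an isotropic free-water compartment of fixed
diffusivity 3e-3 mm^2/s. Constrained nonlinear least squares yields the
parenchymal volume fraction `f_par` (pVF) and the parenchymal FA and MD
(pFA, pMD), which — unlike the single-compartment FA and MD — remain
faithful to the tissue when free water increases.

Around the fit, the package provides the full group analysis:

- **morphometry** — log-Jacobian-determinant (logJ) maps of
  subject-to-template warps (logJ < 0 = locally smaller than template);
- **voxelwise stats** — GLM t-maps with nuisance covariates, TFCE
  (E=0.5, H=2, 26-connectivity), Freedman–Lane permutation FWE at 5%,
  and Hedge's g effect-size maps;
- **ROI reporting** — whole-brain and FA>0.2 WM masks, per-region
  Qvoxels / peak-t / peak-g tables with the Qvoxels >= 0.1 listing rule;
- **clinical correlation** — region-mean metrics vs the SARA ataxia
  score, Pearson r with a 13-test Benjamini–Hochberg FDR family;
- **synthetic data** — a phantom cohort (14 controls vs 13 patients,
  10 x b0 / 10 x b300 / 60 x b1100 s/mm^2, Rician noise) with focal
  CSF-adjacent parenchymal loss, diffuse pMD/pFA shifts, focal atrophy
  warps, and a SARA score generated from truth cerebellar pVF.

See `docs/methods.md` for assumptions, parameter defaults, and limits.

## Worked example

Fit one voxel whose signal was generated with 85% parenchyma
(WM-like tensor, eigenvalues (1.5, 0.4, 0.4)e-3 mm^2/s) and 15% free
water:

```python
import numpy as np
import pardti as p

scheme = p.build_default_scheme(seed=0)          # 80-volume multi-shell
D = np.diag([1.5e-3, 0.4e-3, 0.4e-3])
signal = p.predict_dual(1000.0, 0.85, D, scheme)

fit = p.fit_dual_nls(signal, scheme)
print(f"pVF={fit.f_par:.3f}  pMD={p.md_of(fit.d_par):.3e}  "
      f"pFA={p.fa_of(fit.d_par):.3f}")
```

prints

```
pVF=0.850  pMD=7.667e-04  pFA=0.686
```

recovering the generating fraction and tensor exactly. The free-water
confound this corrects is visible on a heavily contaminated voxel
(`f_par=0.6`): the single-compartment fit reports MD 1.172e-3 and
FA 0.476 — a 53% MD inflation and 0.21 FA loss that are pure
partial-volume artifact — while the dual fit returns pMD 7.667e-4,
pFA 0.686, pVF 0.600, the true tissue values.

A full synthetic study runs as

```python
from pardti.phantom import simulate_cohort
from pardti.pipeline import run_group_analysis

dataset = simulate_cohort(seed=11)               # 14 HV + 13 patients
result = run_group_analysis(dataset, n_perm=250, seed=3)
print(result.tables["pVF"])                      # Qvoxels >= 0.1 table
print(result.correlations)                       # 13-test FDR family
```

which reproduces the expected dissociation: pVF loss and logJ decreases
significant only in the CSF-adjacent / contracted cerebellum and
brainstem, pMD increases and pFA decreases also in deep cerebral tissue,
and a negative cerebellar pVF–SARA correlation.

The same operations are available from the shell via the `pardti` CLI
(`simulate`, `fit`, `dtbm`, `stats`, `report`, `correlate`).

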