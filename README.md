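# dotfrac

Sphere ("dot") signal-fraction mapping from ultra-high-b spherical b-tensor
encoded diffusion MRI, with synthetic phantoms, ROI aggregation and group
statistics.

## The problem

Cerebellar grey matter contains small, roughly spherical water compartments
(candidates include granule-cell somata and dendritic structures) whose
apparent diffusivity is very low in *every* direction. Spherical tensor
encoding (STE) sensitises each diffusion measurement isotropically, so at
ultra-strong weightings (b ≥ 10,000 s/mm²) signal from axons and other
elongated structures is suppressed and a slowly decaying residual from these
"dot-like" compartments remains. Mapping that residual gives a candidate
in-vivo proxy for cell-body density — of interest in movement disorders
(spinocerebellar ataxia, dystonia, Parkinson's disease) where cerebellar
grey-matter pathology is implicated but conventional morphometry and DTI are
insensitive or non-specific.

`dotfrac` implements the per-voxel estimation, the cerebellar ROI
aggregation and the cohort statistics for this analysis, plus a synthetic
phantom/cohort generator so that every stage is testable without scanner
data.

## The model

Assuming non-exchanging Gaussian compartments, the STE signal is a sum of
isotropic exponentials,

    S(b) = S0 · Σᵢ fᵢ · exp(−b·Dᵢ),

with b in s/mm², diffusivities in μm²/ms (1000 s/mm² ≡ 1 ms/μm²). Two
regimes of this decay are fitted per voxel, by bounded trust-region
nonlinear least squares:

* **high b** (b ≥ 10,000 s/mm²): mono-exponential `S0ₛ·exp(−b·Dₛ)` —
  intercept S0ₛ and diffusivity Dₛ of the sphere compartment;
* **low b** (b ≤ 1,500 s/mm²): free-water elimination
  `S0·[fₜ·exp(−b·MD) + (1−fₜ)·exp(−b·3)]` with the CSF diffusivity fixed at
  3 μm²/ms — tissue fraction fₜ, free-water-corrected tissue MD, and S0.

The free-water-eliminated sphere signal fraction is then

    fₛ = S0ₛ / (fₜ·S0).

Downstream, voxels are filtered (fₜ > 0.3; fₛ and Dₛ within the per-subject
99th percentile), summarised as medians per cerebellar lobule (I–X) and per
lobe (anterior, superior/inferior posterior, flocculonodular; lobe medians
pool voxels, regions with < 5 voxels are excluded), and compared across
groups with Mann-Whitney tests, ICC(2,1) scan–rescan reproducibility,
covariate-adjusted regression, one-way ANOVA + Tukey HSD, and Bonferroni
thresholding (0.05/15 ≈ 0.0033).

## Worked example

The three-compartment grey-matter benchmark (free water f=0.2, D=3; tissue
f=0.72, D=1; sphere f=0.08, D=0.1 μm²/ms):

```python
import numpy as np
from dotfrac import (CompartmentMixture, fit_highb_monoexp,
                     fit_lowb_freewater, compute_fs)

mix = CompartmentMixture((0.2, 0.72, 0.08), (3.0, 1.0, 0.1))
high_b = np.array([10500., 12000., 13500., 15000.])   # s/mm^2
low_b = np.array([0., 250., 1500.])

s0s, ds, _ = fit_highb_monoexp(mix.signal(high_b), high_b)
s0, ft, md, _ = fit_lowb_freewater(mix.signal(low_b), low_b)
print(f"sphere:  S0s = {s0s:.4f}   Ds = {ds:.4f} um^2/ms")
print(f"tissue:  S0  = {s0:.4f}   ft = {ft:.4f}   MD = {md:.4f} um^2/ms")
print(f"sphere fraction fs = {compute_fs(s0s, ft, s0):.4f}")
```

prints

```
sphere:  S0s = 0.0802   Ds = 0.1002 um^2/ms
tissue:  S0  = 1.0000   ft = 0.7487   MD = 0.7899 um^2/ms
sphere fraction fs = 0.1071
```

The high-b fit recovers the generating sphere parameters (0.08, 0.1) to
within 0.3% — the residual offset is the analytically bounded contamination
of the D=1 compartment at b ≥ 10 ms/μm². The low-b values are the exact
least-squares solution of the bi-exponential model on tri-exponential
tissue: fₜ is *not* the generating 0.8 because intra-tissue decay is itself
multi-exponential (see `docs/methods.md`).

The same pipeline runs end-to-end from the shell:

```sh
dotfrac simulate --out cohort/ --seed 1          # synthetic cohort (NIfTI + scheme + covariates)
dotfrac fit cohort/control-001_dwi.nii.gz cohort/control-001_scheme.txt --out maps/
dotfrac roi maps/ cohort/labels.nii.gz --out roi.csv
dotfrac stats roi.csv cohort/covariates.csv --out stats.csv
```

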