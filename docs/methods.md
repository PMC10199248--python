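# Methods

## Signal model and assumptions

All estimation assumes the spherical-tensor-encoded (STE) signal of a voxel
is a sum of non-exchanging Gaussian compartments, each contributing a single
isotropic apparent diffusivity: `S(b) = S0 Σ f_i exp(−b D_i)`. Exchange
between compartments, microscopic kurtosis, relaxation (TE/T2) weighting and
noise correlations are not modelled. b-values are stored in s/mm² and
converted once, at the model boundary, to ms/μm² (1000 s/mm² = 1 ms/μm²), so
diffusivities are in μm²/ms throughout.

Two regimes of the decay are fitted independently per voxel:

* high b (default cutoff 10,000 s/mm²): `S0s·exp(−b·Ds)`, the isotropically
  restricted "sphere"/dot compartment. Bounds S0s ≥ 0, Ds ∈ [0, 1] μm²/ms.
* low b (default cutoff 1,500 s/mm², b=0 included):
  `S0·[ft·exp(−b·MD) + (1−ft)·exp(−b·D_fw)]` with the free-water
  diffusivity fixed at D_fw = 3 μm²/ms. Bounds ft ∈ [0, 1], MD ∈ [0, 3],
  S0 > 0.

Both are bounded nonlinear least squares (trust-region-reflective,
`scipy.optimize.least_squares`), initialised from log-linear regression of
the positive samples (low-b additionally: ft = 0.9, S0 = mean b0). The
sphere fraction of the tissue signal is `fs = S0s/(ft·S0)`; it is defined
only where both fits converged and ft·S0 > 0 (elsewhere NaN, never an
exception).

### Degenerate voxels

Two boundary degeneracies of the low-b model are handled by an active-set
polish: when the solver stalls near ft = 1 (pure tissue; the free-water term
vanishes) the reduced mono-exponential is refitted with ft pinned at 1, and
when it stalls near ft = 0 *or* MD → D_fw (the two compartments become
indistinguishable) the pure-free-water model is solved in closed form with
ft pinned at 0. The pinned solution is kept only if its residual is no
worse. In the ft = 0 case MD is unidentifiable and the unpinned estimate is
reported with ft = 0; fs is then undefined.

## Acquisition scheme

The default scheme uses the eleven STE shells
b = 250…15,000 s/mm² (step 1,500 above 1,500), shell order randomised by a
seed, and a b=0 volume at every 15th position for drift tracking. Per-shell
repeat counts are a configuration list; the default,
(2, 2, 3, 3, 4, 4, 5, 6, 7, 8, 9) from low to high b, is this package's own
choice — repeats grow with b to balance the SNR loss of stronger weighting —
and is not taken from any published protocol. Fitting requires at least two
distinct non-zero shells at or below the low-b cutoff and two at or above
the high-b cutoff; this is validated before any voxel is fitted.

## Preprocessing

* **Noise level.** If no sigma map is supplied, σ is estimated per voxel
  from the repeats of the highest shell (standard deviation of repeats,
  divided by √(2−π/2) where the apparent SNR is below 2, i.e. the Rayleigh
  regime).
* **Elementwise Rician correction** (`rician_correct`):
  `Â = sqrt(max(M² − 2σ², 0))`, the method-of-moments inversion of
  E[M²] = A² + 2σ². It is the identity at σ = 0, monotone in M, and removes
  the noise plateau, but its *mean* still under-tracks A at per-measurement
  SNR ≲ 2 (Monte-Carlo: E[Â]/A ≈ 0.79–0.85 at SNR 0.9–1.4).
* **Shell-level correction in the pipeline.** Because the high-b shells of
  a realistic acquisition sit at per-measurement SNR near 1, `fit_voxelwise`
  does not fit elementwise-corrected samples. Instead it collapses the
  surviving repeats of each shell to `sqrt(max(mean(M²) − 2σ², 0))` — the
  same moment identity applied where it is exact (the mean over repeats of
  M² is unbiased for A² + 2σ²) — and fits one datum per shell. Since the
  square root is monotone, the shell value is approximately median-unbiased
  even at unit SNR; Monte-Carlo at the default conditions gives median
  biases of about +4% (S0s) and +8% (Ds), versus −27% (S0s) when fitting
  elementwise-corrected repeats. Without a sigma map (or with
  `shell_rician=False`) the plain shell mean is used.
* **Drift.** A quadratic (configurable order 1–3) polynomial in acquisition
  index is fitted to the spatial-mean intensity of the interleaved b0
  volumes; every volume is divided by the fitted gain normalised to the
  first b0. At least three b0s are required.
* **Outliers.** Within each voxel, repeats of a shell (≥ 3 repeats) are
  scored with the modified Z-score `0.6745·(x−median)/MAD` (mean-absolute-
  deviation fallback with constant 0.7979 when MAD = 0); scores above 3.5
  in magnitude are excluded before aggregation. Scoring per shell, rather
  than across all volumes of a voxel, keeps the comparison within an
  exchangeable set; the threshold and the unit are configurable.

## Synthetic data

The phantom is a small cubic grid (default 24³, 4 mm voxels) of concentric
shells: a CSF rim, a grey-matter shell split into ten polar-angle bands
standing in for lobules I–X (band X thinnest, so the small-ROI exclusion
rule is exercisable), and a white-matter core. Default mixtures: GM
f = (0.2, 0.72, 0.08), D = (3, 1, 0.1); WM f = (0.05, 0.9, 0.05),
D = (3, 0.8, 0.05); CSF pure free water. Noise is Rician
(|S + ε₁ + iε₂|, ε ~ N(0, σ²)) with σ defaulting to S0/50 — i.e. b0 SNR 50,
a plausible value for large isotropic voxels on an ultra-strong gradient
system; at the top shell this puts each measurement at SNR ≈ 1, which is
the regime the shell-level correction is designed for. Temporal drift
defaults to a quadratic gain falling from 1 to 0.95 across the scan.

Truth maps use the generating convention: ft = 1 − (free-water fraction),
Ds = diffusivity of the most restricted compartment, fs = (sphere
fraction)/ft, MD = fraction-weighted diffusivity of the non-free-water
compartments. Note that the low-b estimator's target differs from this
convention whenever tissue is internally multi-exponential: for the default
GM mixture the asymptotic (noiseless) estimates are ft = 0.749 and
MD = 0.790 rather than 0.8 and 0.91, and consequently fs = 0.107 rather
than 0.100. Recovery tests therefore compare fitted values against the
noiseless least-squares solution computed by an independent
variable-projection oracle (profile the nonlinear diffusivity on a grid,
solve the amplitudes by NNLS/closed form, polish with Brent), and noise-
robustness is measured against the same noiseless estimand so that it
isolates noise-induced distortion from this deterministic model mismatch.

Cohorts draw each subject's grey-matter (MD, fs) log-normally around group
targets (log-normal keeps parameters positive; the scale is set so the
median absolute deviation matches the group's MAD target), then jitter each
lobule around the subject value with half the between-subject scale — a
one-time choice emulating regional heterogeneity, which also makes the
per-(subject, lobule) medians the natural observational unit for group
comparisons. Group defaults are a healthy-control-like group
(MD 0.60 (0.03) μm²/ms, fs 0.11 (0.01), cerebellar volume 115.9 (21.0) cm³)
and an ataxia-like group (MD 0.54 (0.07), fs 0.14 (0.03), volume
89.6 (12.9)). A simulated total cerebellar volume is attached as covariate.
What the generator does **not** emulate: realistic cerebellar folia
geometry, partial-volume gradients at tissue borders, motion/eddy/
susceptibility artefacts, exchange, spatially varying coil sensitivity.
Passing tests on these phantoms therefore validate the estimation and
aggregation machinery, not robustness to those real-data effects.

## ROI aggregation

Voxel inclusion: labelled grey matter, finite parameters, ft > 0.3, and fs
and Ds at or below the per-subject 99th percentile. The percentile is
computed across all labelled GM of the subject *after* the ft filter (so
CSF-dominated voxels cannot distort the trim point) and "within the 99th
percentile" is read as an upper-tail trim. Both thresholds, the percentile,
and the filter order are configurable.

Medians of MD, fs, Ds are reported per lobule, per lobe, and for the whole
labelled cerebellum. Lobe values pool the voxels of their lobules before
taking the median (pooling ≠ mean of lobule medians; a unit test pins the
distinction). Regions with fewer than 5 included voxels are flagged
excluded and carry no value — in practice this removes the tiny
flocculonodular lobe. The default lobule→lobe table is anterior = I–V,
superior posterior = VI–VII, inferior posterior = VIII–IX,
flocculonodular = X, following standard cerebellar atlas groupings; it is a
configuration table (2-column CSV in the CLI).

## Statistics

* Mann-Whitney U, two-sided; exact null distribution when the combined
  sample is ≤ 20 and tie-free, otherwise normal approximation with tie and
  continuity correction.
* ICC(2,1): two-way random effects, absolute agreement, single measurement,
  computed from the ANOVA mean squares. This form is the standard choice
  for scan–rescan reproducibility of a single measurement per session; it
  penalises systematic shifts between sessions.
* One-way ANOVA with Tukey HSD post-hoc (studentized-range adjustment,
  pooled error variance).
* Covariate-adjusted contrasts: OLS of the outcome on group indicators plus
  total cerebellar volume; the reference group is the first alphabetically
  unless specified.
* Bonferroni: α_adj = α/m with m configurable. The default m = 15
  reconstructs an operative threshold of 0.05/15 ≈ 0.0033 (three metrics ×
  five region-level analyses); m is a configuration value, not a derived
  fact.

## Problem sizes used by the test suite

Exact round-trips run on a 12³ noiseless phantom; noise-robustness on the
24³ phantom's grey-matter shell (≈ 2,800 voxels, chosen so the sampling
error of the voxel-median is a few percent, since per-voxel sphere
estimates at unit SNR are heavy-tailed); cohort power on 100 replicates of
20 + 20 subjects at 16³ without signal synthesis (truth maps through the
ROI and statistics layers); null calibration on 1,000 replicates of 15 + 15.

## Known limitations

* fs inherits a deterministic offset whenever tissue is internally
  multi-exponential (see above); against real tissue it is additionally
  protocol-dependent and, because exchange is not modelled, is expected to
  understate histological volume fractions.
* Per-voxel high-b estimates at b0-SNR 50 are heavy-tailed (a quarter of GM
  voxels can pin Ds at a bound); medians over ROIs are the intended
  consumption unit, single-voxel values are not reliable.
* The drift model is a global polynomial gain; spatially varying drift or
  motion between volumes is out of scope (data are assumed co-registered).
* No resampling/registration: signal, label, sigma and effective-b volumes
  must share the voxel grid.
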