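"""Synthetic phantoms and cohorts with the structure the analysis assumes.

The phantom is a small 3-D grid of concentric tissue shells: a CSF rim, a
grey-matter shell subdivided into ten lobule-like labels (I-X) by polar
angle, and a white-matter core. Each tissue class carries an isotropic
:class:`~dotfrac.signal_model.CompartmentMixture`; the voxel signal is the
forward model evaluated on the acquisition scheme, multiplied by a smooth
temporal drift gain, then Rician-corrupted (|S + e1 + i*e2| with
e ~ N(0, sigma^2)). Cohorts perturb the grey-matter mixture per subject
(log-normally, keeping parameters positive) so group medians of the truth
maps approach configurable targets, and attach a simulated total cerebellar
volume covariate.

Truth :class:`~dotfrac.maps.ParameterMaps` use the generating-mixture
convention: ft = 1 - (free-water fraction), Ds = diffusivity of the most
restricted compartment, fs = (sphere fraction)/ft, MD = fraction-weighted
mean diffusivity over the non-free-water compartments. Compartments with
D >= the free-water diffusivity count as free water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import DwiDataset
from .maps import ParameterMaps
from .scheme import AcquisitionScheme
from .signal_model import FREE_WATER_DIFFUSIVITY, CompartmentMixture

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "SubjectRecord",
    "default_geometry",
    "default_mixtures",
    "default_phantom",
    "generate_phantom",
    "generate_cohort",
    "truth_values",
    "DEFAULT_SIGMA_FRACTION",
    "DEFAULT_DRIFT",
    "DEFAULT_LOBE_OF_LABEL",
]

#: Rician noise level as a fraction of the b=0 signal (SNR 50 at b0)
DEFAULT_SIGMA_FRACTION = 0.02

#: quadratic drift gain over normalised acquisition index: 1 at the start,
#: 0.95 at the end of the scan (coefficients low order first)
DEFAULT_DRIFT = (1.0, 0.0, -0.05)

#: lobule label -> cerebellar lobe (anterior, superior/inferior posterior,
#: flocculonodular); I-V anterior, VI-VII superior posterior, VIII-IX
#: inferior posterior, X flocculonodular
DEFAULT_LOBE_OF_LABEL = {1: "A", 2: "A", 3: "A", 4: "A", 5: "A",
                         6: "SP", 7: "SP", 8: "IP", 9: "IP", 10: "F"}

_WM_LABEL = 101
_CSF_LABEL = 102


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue mixtures and corruption model of one phantom."""

    labels: np.ndarray  # 3-D int array; 0 = background
    tissue_of_label: dict  # label -> tissue class name
    mixtures: dict  # class name -> CompartmentMixture
    sigma: float = DEFAULT_SIGMA_FRACTION  # Rician noise as fraction of S0
    drift: tuple = DEFAULT_DRIFT  # polynomial gain coefficients over acq_index/(n-1)
    seed: int = 0

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D integer volume")
        present = set(np.unique(labels)) - {0}
        if not present:
            raise ValueError("label layout is empty")
        missing = present - set(self.tissue_of_label)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no tissue class")
        missing_mix = set(self.tissue_of_label.values()) - set(self.mixtures)
        if missing_mix:
            raise ValueError(f"tissue classes {sorted(missing_mix)} have no mixture")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "labels", labels)

    def drift_gain(self, acq_indices) -> np.ndarray:
        t = np.asarray(acq_indices, dtype=float)
        span = max(t.max(), 1.0)
        gain = np.polynomial.polynomial.polyval(t / span, np.asarray(self.drift, float))
        if np.any(gain <= 0):
            raise ValueError("drift gain must stay positive over the scheme")
        return gain


def truth_values(mixture: CompartmentMixture, d_fw: float = FREE_WATER_DIFFUSIVITY):
    """Generating-convention truth (md, ft, s0, s0s, ds, fs) of a mixture."""
    f = np.asarray(mixture.fractions)
    d = np.asarray(mixture.diffusivities)
    fw = d >= d_fw - 1e-9
    ft = float(f[~fw].sum())
    if ft <= 0:
        return np.nan, 0.0, mixture.s0, np.nan, np.nan, np.nan
    md = float((f[~fw] * d[~fw]).sum() / ft)
    sphere = int(np.argmin(d))
    ds = float(d[sphere])
    f_s = float(f[sphere]) if not fw[sphere] else 0.0
    fs = f_s / ft
    s0s = mixture.s0 * f_s
    return md, ft, mixture.s0, s0s, ds, fs


def default_geometry(shape: int | tuple = 24):
    """Concentric-shell lobule geometry: CSF rim, 10-lobule GM shell, WM core.

    The GM shell is split into ten polar-angle bands labelled 1..10 (lobule
    X, the flocculonodular band, is the thinnest so the small-ROI rule is
    exercisable). Returns ``(labels, tissue_of_label)``.
    """
    if np.isscalar(shape):
        shape = (int(shape),) * 3
    nx, ny, nz = shape
    c = (np.array(shape) - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
    r_max = min(shape) / 2.0 - 0.5
    labels = np.zeros(shape, dtype=int)
    inside = r <= r_max
    labels[inside & (r > 0.85 * r_max)] = _CSF_LABEL
    gm = inside & (r > 0.55 * r_max) & (r <= 0.85 * r_max)
    labels[inside & (r <= 0.55 * r_max)] = _WM_LABEL
    # polar angle from +z in [0, pi] -> ten bands; band 10 narrowed
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip((z - c[2]) / np.where(r > 0, r, 1.0), -1, 1))
    edges = np.concatenate([np.linspace(0, 0.97 * np.pi, 10), [np.pi]])
    band = np.clip(np.digitize(theta, edges[1:-1]) + 1, 1, 10)
    labels[gm] = band[gm]
    tissue = {lab: "GM" for lab in range(1, 11)}
    tissue[_WM_LABEL] = "WM"
    tissue[_CSF_LABEL] = "CSF"
    return labels, tissue


def default_mixtures() -> dict:
    """Literature-style tissue mixtures (fractions, diffusivities um^2/ms)."""
    return {
        # free water + tissue + restricted sphere
        "GM": CompartmentMixture((0.2, 0.72, 0.08), (3.0, 1.0, 0.1)),
        "WM": CompartmentMixture((0.05, 0.90, 0.05), (3.0, 0.8, 0.05)),
        "CSF": CompartmentMixture((1.0,), (3.0,)),
    }


def default_phantom(shape: int | tuple = 24, sigma: float = DEFAULT_SIGMA_FRACTION,
                    drift: tuple = DEFAULT_DRIFT, seed: int = 0) -> PhantomSpec:
    labels, tissue = default_geometry(shape)
    return PhantomSpec(labels, tissue, default_mixtures(), sigma=sigma,
                       drift=drift, seed=seed)


def _truth_maps(spec: PhantomSpec) -> ParameterMaps:
    grid = spec.labels.shape
    arrays = {k: np.full(grid, np.nan) for k in ("md", "ft", "s0", "s0s", "ds", "fs")}
    conv = np.zeros(grid, dtype=bool)
    for label, tissue in spec.tissue_of_label.items():
        sel = spec.labels == label
        md, ft, s0, s0s, ds, fs = truth_values(spec.mixtures[tissue])
        for key, val in zip(("md", "ft", "s0", "s0s", "ds", "fs"),
                            (md, ft, s0, s0s, ds, fs)):
            arrays[key][sel] = val
        conv[sel] = True
    return ParameterMaps(**arrays, converged_low=conv, converged_high=conv)


def generate_phantom(spec: PhantomSpec, scheme: AcquisitionScheme,
                     rng: np.random.Generator | None = None):
    """Simulate a 4-D dataset from a phantom spec, with its truth maps.

    Per voxel the noiseless signal is the forward model of the voxel's
    tissue mixture, scaled by the drift gain at each volume's acquisition
    index, then Rician-corrupted. Background voxels are zero (noise-free).
    Reproducible: the same spec and seed give bit-identical data.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = spec.labels.shape
    n_vol = len(scheme)
    gain = spec.drift_gain(scheme.acq_indices)
    b = scheme.b_values

    signal = np.zeros(grid + (n_vol,))
    for tissue, mixture in spec.mixtures.items():
        sel = np.isin(spec.labels, [lab for lab, t in spec.tissue_of_label.items() if t == tissue])
        if not sel.any():
            continue
        signal[sel] = mixture.signal(b) * gain

    s0_ref = max(m.s0 for m in spec.mixtures.values())
    sigma_abs = spec.sigma * s0_ref
    if sigma_abs > 0:
        fg = spec.labels > 0
        noisy = np.abs(
            signal[fg] + sigma_abs * rng.standard_normal(signal[fg].shape)
            + 1j * sigma_abs * rng.standard_normal(signal[fg].shape)
        )
        signal[fg] = noisy
    sigma_map = np.where(spec.labels > 0, sigma_abs, 0.0)
    dataset = DwiDataset(signal, scheme, sigma_map=sigma_map)
    return dataset, _truth_maps(spec)


# --- cohorts ----------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Targets for one cohort group, in truth-map units.

    Medians and median absolute deviations (MAD) describe the between-
    subject distribution of grey-matter MD (um^2/ms), sphere fraction fs,
    and total cerebellar volume (cm^3).
    """

    name: str
    n_subjects: int
    md_median: float = 0.60
    md_mad: float = 0.03
    fs_median: float = 0.11
    fs_mad: float = 0.01
    volume_median: float = 115.9
    volume_mad: float = 21.0
    #: within-subject regional (lobule-to-lobule) spread, as a fraction of
    #: the between-subject log-normal scale
    regional_spread_frac: float = 0.5

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.md_median < 3:
            raise ValueError("target MD must lie in (0, 3) um^2/ms")
        if not 0 < self.fs_median < 1:
            raise ValueError("target fs must lie in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    template: PhantomSpec
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("cohort needs at least one group")


@dataclass
class SubjectRecord:
    subject: str
    group: str
    dataset: DwiDataset | None
    truth: ParameterMaps
    covariates: dict


def _lognormal_sigma(median: float, mad: float) -> float:
    """Log-normal shape parameter whose median absolute deviation ~= mad."""
    if mad <= 0:
        return 0.0
    return float(np.log1p(mad / median) / 0.6745)


def _subject_gm_mixture(template_gm: CompartmentMixture, md: float, fs: float,
                        d_fw: float = FREE_WATER_DIFFUSIVITY) -> CompartmentMixture:
    """Grey-matter mixture hitting generating-truth (md, fs) exactly.

    Keeps the template's free-water fraction and sphere diffusivity and
    solves for the sphere fraction and tissue diffusivity.
    """
    _, ft, s0, _, ds, _ = truth_values(template_gm, d_fw)
    if ft <= 0 or len(template_gm.fractions) < 3:
        raise ValueError("template GM mixture must contain a tissue and a sphere compartment")
    f_fw = 1.0 - ft
    f_s = fs * ft
    f_t = ft - f_s
    if f_t <= 0:
        raise ValueError(f"fs target {fs} unreachable: sphere fraction exceeds tissue fraction")
    d_t = (md * ft - f_s * ds) / f_t
    if d_t <= 0 or d_t >= d_fw:
        raise ValueError(
            f"MD target {md} unreachable with sphere diffusivity {ds} and ft {ft}"
        )
    return CompartmentMixture((f_fw, f_t, f_s), (d_fw, d_t, ds), s0=s0)


def generate_cohort(spec: CohortSpec, scheme: AcquisitionScheme,
                    with_signal: bool = True) -> list[SubjectRecord]:
    """Generate per-subject datasets/truth maps with group-level structure.

    Subject grey matter is resampled log-normally around each group's MD/fs
    targets (spread set by the MAD targets), and each grey-matter lobule is
    additionally jittered around the subject value (scale
    ``regional_spread_frac`` times the between-subject scale), emulating
    regional heterogeneity; cohort medians of the truth maps approach the
    group targets. ``with_signal=False`` skips the 4-D signal synthesis
    (truth maps and covariates only), which is enough for statistical power
    studies of the downstream ROI/statistics layers.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    template_gm = template.mixtures["GM"]
    gm_labels = sorted(
        lab for lab, t in template.tissue_of_label.items()
        if t == "GM" and (template.labels == lab).any()
    )
    if not gm_labels:
        raise ValueError("template phantom has no grey-matter voxels")
    records = []
    for g in spec.groups:
        s_md = _lognormal_sigma(g.md_median, g.md_mad)
        s_fs = _lognormal_sigma(g.fs_median, g.fs_mad)
        s_vol = _lognormal_sigma(g.volume_median, g.volume_mad)
        for i in range(g.n_subjects):
            md = g.md_median * np.exp(s_md * rng.standard_normal())
            fs = g.fs_median * np.exp(s_fs * rng.standard_normal())
            fs = float(np.clip(fs, 1e-3, 0.9))
            md = float(np.clip(md, 1e-3, 2.9))
            vol = g.volume_median * np.exp(s_vol * rng.standard_normal())
            # per-lobule regional jitter around the subject values
            mixtures = dict(template.mixtures)
            tissue_of_label = dict(template.tissue_of_label)
            for lab in gm_labels:
                md_l = float(np.clip(
                    md * np.exp(g.regional_spread_frac * s_md * rng.standard_normal()),
                    1e-3, 2.9))
                fs_l = float(np.clip(
                    fs * np.exp(g.regional_spread_frac * s_fs * rng.standard_normal()),
                    1e-3, 0.9))
                name = f"GM{lab}"
                mixtures[name] = _subject_gm_mixture(template_gm, md_l, fs_l)
                tissue_of_label[lab] = name
            subj_spec = replace(
                template,
                mixtures=mixtures,
                tissue_of_label=tissue_of_label,
                seed=int(rng.integers(2**31 - 1)),
            )
            subject = f"{g.name}-{i + 1:03d}"
            if with_signal:
                dataset, truth = generate_phantom(subj_spec, scheme)
            else:
                dataset, truth = None, _truth_maps(subj_spec)
            records.append(SubjectRecord(
                subject, g.name, dataset, truth,
                {"subject": subject, "group": g.name,
                 "cerebellar_volume": float(vol)},
            ))
    return records


def cohort_covariates(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.covariates for r in records])
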