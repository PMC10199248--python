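"""Per-voxel preprocessing: noise level, Rician floor, drift, outliers.

Magnitude MRI noise is Rician: at low SNR the measured magnitude plateaus
above the true decaying signal, biasing high-b fits. The correction used
here is the method-of-moments identity E[M^2] = A^2 + 2 sigma^2, inverted
elementwise as A_hat = sqrt(max(M^2 - 2 sigma^2, 0)). Slow scanner drift is
tracked on the interleaved b=0 volumes and divided out as a smooth gain in
acquisition order. Signal outliers are scored with the Iglewicz-Hoaglin
modified Z-score and excluded above a threshold (default 3.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DwiDataset

__all__ = [
    "OutlierReport",
    "estimate_sigma",
    "rician_correct",
    "drift_correct",
    "modified_zscore",
]

#: magnitude-domain std of a Rayleigh (A=0 Rician) variate is sigma*sqrt(2 - pi/2)
_RAYLEIGH_STD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))

#: consistency constant relating mean absolute deviation to the normal sigma
_MEANAD_CONSTANT = 0.7979


@dataclass(frozen=True)
class OutlierReport:
    """Modified Z-scores with exclusion flags at a fixed threshold."""

    scores: np.ndarray
    excluded: np.ndarray
    threshold: float

    def __post_init__(self):
        if self.scores.shape != self.excluded.shape:
            raise ValueError("scores and excluded must have the same shape")


def modified_zscore(values, threshold: float = 3.5) -> OutlierReport:
    """Score values with the modified Z-score 0.6745*(x - median)/MAD.

    MAD is the median absolute deviation from the median; when it is zero
    (at least half the values identical) the mean absolute deviation with
    consistency constant 0.7979 is used instead. Values scoring above
    ``threshold`` in magnitude are flagged for exclusion. Fewer than 3
    values cannot be scored: an empty report is returned.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        empty = np.empty(0)
        return OutlierReport(empty, np.empty(0, dtype=bool), threshold)
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        scores = 0.6745 * dev / mad
    else:
        meanad = np.mean(np.abs(dev))
        scores = _MEANAD_CONSTANT * dev / meanad if meanad > 0 else np.zeros_like(dev)
    return OutlierReport(scores, np.abs(scores) > threshold, threshold)


def estimate_sigma(dataset: DwiDataset, min_repeats: int = 3) -> np.ndarray:
    """Per-voxel Rician noise level from repeats of the highest-b shell.

    The highest shell carries the least true signal, so the spread of its
    repeats is dominated by noise. The raw per-voxel standard deviation is
    corrected for Rayleigh-regime inflation where the apparent SNR
    (mean/std) is below 2, using std = sigma*sqrt(2 - pi/2) at A=0.
    """
    b = dataset.scheme.b_values
    top = b.max()
    cols = np.flatnonzero(b == top)
    if cols.size < min_repeats:
        raise ValueError(
            f"highest shell b={top:g} has only {cols.size} repeats (< {min_repeats}); "
            "supply a sigma_map instead"
        )
    rep = dataset.signal[..., cols]
    std = rep.std(axis=-1, ddof=1)
    mean = rep.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        low_snr = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.inf) < 2.0
    sigma = np.where(low_snr, std / _RAYLEIGH_STD_FACTOR, std)
    return sigma


def rician_correct(dataset: DwiDataset, sigma_map: np.ndarray | None = None) -> DwiDataset:
    """Remove the Rician noise floor from every measurement.

    Applies A_hat = sqrt(max(M^2 - 2 sigma^2, 0)) elementwise, with sigma
    taken from ``sigma_map``, then ``dataset.sigma_map``, then
    :func:`estimate_sigma` in that order. With sigma = 0 this is the
    identity. The operation is monotone in M and idempotent on noiseless
    data.
    """
    if sigma_map is None:
        sigma_map = dataset.sigma_map
    if sigma_map is None:
        sigma_map = estimate_sigma(dataset)
    sigma_map = np.asarray(sigma_map, dtype=float)
    if sigma_map.shape != dataset.grid:
        raise ValueError(f"sigma_map shape {sigma_map.shape} != grid {dataset.grid}")
    if np.any(sigma_map < 0):
        raise ValueError("sigma must be non-negative")
    m2 = dataset.signal**2 - 2.0 * (sigma_map**2)[..., None]
    corrected = np.sqrt(np.clip(m2, 0.0, None))
    out = dataset.with_signal(corrected)
    out.sigma_map = sigma_map
    return out


def fit_drift_gain(dataset: DwiDataset, order: int = 2):
    """Fit a polynomial gain in acq_index to the spatial-mean b0 intensity.

    Returns the per-volume gain (normalised to 1 at the first b0) for every
    volume in the scheme. Requires >= order + 1 interleaved b0s.
    """
    if not 1 <= order <= 3:
        raise ValueError("drift polynomial order must be in 1..3")
    isb0 = dataset.scheme.is_b0
    acq = dataset.scheme.acq_indices.astype(float)
    n_b0 = int(isb0.sum())
    if n_b0 < max(3, order + 1):
        raise ValueError(
            f"drift correction needs >= {max(3, order + 1)} interleaved b0 volumes, "
            f"got {n_b0}"
        )
    b0_mean = dataset.signal[..., isb0].mean(axis=(0, 1, 2))
    # scale acq_index to [0, 1] for conditioning
    span = max(acq.max(), 1.0)
    coeffs = np.polyfit(acq[isb0] / span, b0_mean, order)
    gain = np.polyval(coeffs, acq / span)
    first_b0 = np.flatnonzero(isb0)[0]
    gain = gain / gain[first_b0]
    if np.any(gain <= 0):
        raise ValueError("fitted drift gain is non-positive; data unusable for drift fit")
    return gain


def drift_correct(dataset: DwiDataset, order: int = 2) -> DwiDataset:
    """Divide out slow temporal drift estimated from interleaved b0s.

    A degree-``order`` (default quadratic) polynomial in acquisition index
    is fit to the spatial-mean b0 intensity and every volume is divided by
    the fitted gain, normalised to 1 at the first b0. After correction the
    b0 mean intensity is flat up to noise.
    """
    gain = fit_drift_gain(dataset, order=order)
    return dataset.with_signal(dataset.signal / gain)
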