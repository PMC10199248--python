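"""Isotropic multi-compartment signal model for spherical b-tensor encoding.

Under spherical tensor encoding (STE) every measurement is sensitised to
diffusion in all directions at once, so each non-exchanging Gaussian
compartment contributes a single isotropic apparent diffusivity and the
signal decays as a sum of exponentials::

    S(b) = S0 * sum_i f_i * exp(-b * D_i)

Unit convention (load-bearing throughout the package): b-values are *stored*
in s/mm^2, the units scanners and scheme files use, while diffusivities are
expressed in um^2/ms. The conversion 1000 s/mm^2 == 1 ms/um^2 is applied
exactly once, at this model boundary, so that b*D is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: multiplicative factor converting b in s/mm^2 to ms/um^2
B_S_PER_MM2_TO_MS_PER_UM2 = 1.0e-3

#: conventional free-water diffusivity at body temperature, um^2/ms
FREE_WATER_DIFFUSIVITY = 3.0

__all__ = [
    "B_S_PER_MM2_TO_MS_PER_UM2",
    "FREE_WATER_DIFFUSIVITY",
    "CompartmentMixture",
    "forward_signal",
    "compute_fs",
]


def b_to_ms_per_um2(b_s_per_mm2):
    """Convert b-values from s/mm^2 to ms/um^2 (the internal fit units)."""
    return np.asarray(b_s_per_mm2, dtype=float) * B_S_PER_MM2_TO_MS_PER_UM2


@dataclass(frozen=True)
class CompartmentMixture:
    """A normalised mixture of isotropic Gaussian diffusion compartments.

    Parameters
    ----------
    fractions
        Signal fractions, each >= 0, summing to one (within 1e-9).
    diffusivities
        Isotropic apparent diffusivities in um^2/ms, each >= 0, one per
        compartment.
    s0
        Non-diffusion-weighted signal amplitude (arbitrary units), > 0.
    """

    fractions: tuple[float, ...]
    diffusivities: tuple[float, ...]
    s0: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.diffusivities, dtype=float)
        if f.ndim != 1 or d.ndim != 1 or f.size == 0:
            raise ValueError("fractions and diffusivities must be non-empty 1-D sequences")
        if f.size != d.size:
            raise ValueError(
                f"got {f.size} fractions but {d.size} diffusivities"
            )
        if np.any(f < 0):
            raise ValueError("signal fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"signal fractions must sum to 1, got {f.sum()!r}")
        if np.any(d < 0):
            raise ValueError("diffusivities must be non-negative")
        if not np.isfinite(self.s0) or self.s0 <= 0:
            raise ValueError("s0 must be finite and positive")
        # normalise to tuples so the dataclass stays hashable/frozen
        object.__setattr__(self, "fractions", tuple(float(x) for x in f))
        object.__setattr__(self, "diffusivities", tuple(float(x) for x in d))

    @property
    def n_compartments(self) -> int:
        return len(self.fractions)

    def signal(self, b_s_per_mm2):
        """Evaluate the forward signal at b-values given in s/mm^2.

        Accepts a scalar or array; returns the same shape.
        """
        b = np.asarray(b_s_per_mm2, dtype=float)
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("b-values must be finite and non-negative")
        b_int = b_to_ms_per_um2(b)
        f = np.asarray(self.fractions)
        d = np.asarray(self.diffusivities)
        out = self.s0 * np.exp(-np.multiply.outer(b_int, d)) @ f
        return out if out.ndim else float(out)


def forward_signal(model: CompartmentMixture, b_s_per_mm2):
    """STE signal of ``model`` at diffusion weighting ``b`` (s/mm^2).

    Returns ``S0 * sum_i f_i * exp(-b * D_i)`` with b converted internally
    to ms/um^2. Non-increasing in b for any valid mixture; equals S0 at b=0.
    """
    return model.signal(b_s_per_mm2)


def compute_fs(s0s, ft, s0):
    """Sphere (dot) signal fraction of the free-water-eliminated tissue signal.

    ``fs = S0,s / (ft * S0)``: the high-b mono-exponential intercept
    normalised by the tissue signal at b=0. Where ``ft * S0 <= 0`` the voxel
    is undefined and NaN is returned rather than raising, so a whole map can
    be computed in one call.

    Parameters are broadcast against each other; scalars in give a scalar
    out.
    """
    s0s = np.asarray(s0s, dtype=float)
    ft = np.asarray(ft, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0s[np.isfinite(s0s)] < 0):
        raise ValueError("S0s must be non-negative where finite")
    denom = ft * s0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        fs = np.where(denom > 0, s0s / np.where(denom > 0, denom, 1.0), np.nan)
    return fs if fs.ndim else float(fs)
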