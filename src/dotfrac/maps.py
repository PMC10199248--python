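"""Per-voxel parameter maps: the pipeline's central product.

Holds the six scalar maps of the two-regime decay analysis -- free-water-
eliminated tissue MD, tissue fraction ft and b=0 signal S0 from the low-b
bi-exponential fit; sphere intercept S0,s and diffusivity Ds from the
high-b mono-exponential fit; and the derived sphere fraction
fs = S0,s/(ft*S0) -- plus per-voxel fit-quality flags and outlier counts.
Voxels where a fit failed carry NaN and a False convergence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ParameterMaps", "write_maps", "read_maps"]

_FLOAT_MAPS = ("md", "ft", "s0", "s0s", "ds", "fs")
_INT_MAPS = ("n_excluded_lowb", "n_excluded_highb")
_BOOL_MAPS = ("converged_low", "converged_high")

# on-disk file names (conventional symbol casing)
_FILE_NAMES = {
    "md": "MD", "ft": "ft", "s0": "S0", "s0s": "S0s", "ds": "Ds", "fs": "fs",
    "n_excluded_lowb": "n_excluded_lowb", "n_excluded_highb": "n_excluded_highb",
    "converged_low": "converged_low", "converged_high": "converged_high",
}


@dataclass
class ParameterMaps:
    md: np.ndarray
    ft: np.ndarray
    s0: np.ndarray
    s0s: np.ndarray
    ds: np.ndarray
    fs: np.ndarray
    n_excluded_lowb: np.ndarray = None
    n_excluded_highb: np.ndarray = None
    converged_low: np.ndarray = None
    converged_high: np.ndarray = None

    def __post_init__(self):
        grid = np.asarray(self.md).shape
        for name in _FLOAT_MAPS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != grid:
                raise ValueError(f"map {name} shape {arr.shape} != {grid}")
            setattr(self, name, arr)
        for name, dtype, default in (
            [(n, int, 0) for n in _INT_MAPS] + [(n, bool, True) for n in _BOOL_MAPS]
        ):
            arr = getattr(self, name)
            arr = np.full(grid, default, dtype=dtype) if arr is None else np.asarray(arr, dtype=dtype)
            if arr.shape != grid:
                raise ValueError(f"map {name} shape {arr.shape} != {grid}")
            setattr(self, name, arr)
        self._check_ranges()

    def _check_ranges(self):
        def finite(a):
            return a[np.isfinite(a)]

        if np.any(finite(self.ft) < -1e-9) or np.any(finite(self.ft) > 1 + 1e-9):
            raise ValueError("ft out of [0, 1]")
        if np.any(finite(self.md) < -1e-9) or np.any(finite(self.md) > 3 + 1e-9):
            raise ValueError("MD out of [0, 3] um^2/ms")
        if np.any(finite(self.ds) < -1e-9):
            raise ValueError("Ds must be >= 0")
        if np.any(finite(self.fs) < -1e-9):
            raise ValueError("fs must be >= 0")

    @property
    def grid(self):
        return self.md.shape

    def defined_fs(self) -> np.ndarray:
        """Mask of voxels where fs carries a value (both fits converged)."""
        return np.isfinite(self.fs)


def write_maps(maps: ParameterMaps, out_dir, voxel_size: float = 4.0) -> None:
    """Write each map as <name>.nii.gz into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    for name, fname in _FILE_NAMES.items():
        arr = getattr(maps, name)
        dtype = np.float32 if name in _FLOAT_MAPS else np.int16
        nib.save(nib.Nifti1Image(arr.astype(dtype), aff), str(out_dir / f"{fname}.nii.gz"))


def read_maps(in_dir) -> ParameterMaps:
    in_dir = Path(in_dir)
    kwargs = {}
    for name, fname in _FILE_NAMES.items():
        path = in_dir / f"{fname}.nii.gz"
        if not path.exists():
            if name in _FLOAT_MAPS:
                raise IOError(f"missing parameter map {path}")
            continue
        kwargs[name] = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    for name in _BOOL_MAPS:
        if name in kwargs:
            kwargs[name] = kwargs[name] > 0.5
    return ParameterMaps(**kwargs)
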