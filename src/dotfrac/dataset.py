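"""4-D diffusion-weighted dataset container and NIfTI/sidecar I/O.

A :class:`DwiDataset` couples the 4-D signal array with its acquisition
scheme and optional per-voxel maps: a Rician noise level ``sigma_map`` (same
units as the signal) and a dimensionless effective-b scaling ``beff_map``
that absorbs gradient nonlinearities (the fit then uses b_eff = b * beff).
The pipeline operates in voxel space: auxiliary maps must share the grid of
the signal and no resampling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .scheme import AcquisitionScheme, read_scheme, write_scheme

__all__ = ["DwiDataset", "read_dataset", "write_dataset"]


@dataclass
class DwiDataset:
    signal: np.ndarray  # (x, y, z, volume), non-negative
    scheme: AcquisitionScheme
    sigma_map: np.ndarray | None = None
    beff_map: np.ndarray | None = None
    voxel_size: float = 4.0  # mm, isotropic

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme has "
                f"{len(self.scheme)}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("signal contains negative values")
        grid = self.signal.shape[:3]
        for name in ("sigma_map", "beff_map"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != grid:
                raise ValueError(
                    f"{name} shape {m.shape} does not match signal grid {grid}"
                )
            setattr(self, name, m)
        if self.sigma_map is not None and np.any(self.sigma_map < 0):
            raise ValueError("sigma_map must be non-negative")
        if self.beff_map is not None and np.any(self.beff_map <= 0):
            raise ValueError("beff_map must be strictly positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def with_signal(self, signal: np.ndarray) -> "DwiDataset":
        """Copy of this dataset with the signal array replaced."""
        return DwiDataset(signal, self.scheme, self.sigma_map, self.beff_map, self.voxel_size)


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    return aff


def _load_nifti(path, expect_ndim=None):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise IOError(f"{path}: expected a {expect_ndim}-D image, got {data.ndim}-D")
    return data, img


def read_dataset(image_path, scheme_path, sigma_path=None, beff_path=None) -> DwiDataset:
    """Load a 4-D DWI NIfTI plus its plain-text scheme sidecar.

    Raises an explicit IOError naming the offending file when the volume
    count disagrees with the scheme or any file is unreadable.
    """
    data, img = _load_nifti(image_path, expect_ndim=4)
    scheme = read_scheme(scheme_path)
    if data.shape[3] != len(scheme):
        raise IOError(
            f"{image_path} has {data.shape[3]} volumes but {scheme_path} lists "
            f"{len(scheme)}"
        )
    sigma = _load_nifti(sigma_path, expect_ndim=3)[0] if sigma_path else None
    beff = _load_nifti(beff_path, expect_ndim=3)[0] if beff_path else None
    voxel_size = float(img.header.get_zooms()[0]) or 4.0
    return DwiDataset(data, scheme, sigma_map=sigma, beff_map=beff, voxel_size=voxel_size)


def write_dataset(dataset: DwiDataset, image_path, scheme_path,
                  sigma_path=None, beff_path=None) -> None:
    """Write signal (float32 NIfTI), scheme sidecar and optional maps."""
    aff = _affine(dataset.voxel_size)
    nib.save(nib.Nifti1Image(dataset.signal.astype(np.float32), aff), str(image_path))
    write_scheme(dataset.scheme, scheme_path)
    if sigma_path is not None and dataset.sigma_map is not None:
        nib.save(nib.Nifti1Image(dataset.sigma_map.astype(np.float32), aff), str(sigma_path))
    if beff_path is not None and dataset.beff_map is not None:
        nib.save(nib.Nifti1Image(dataset.beff_map.astype(np.float32), aff), str(beff_path))
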