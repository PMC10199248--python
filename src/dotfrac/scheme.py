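"""Acquisition schemes: which b-value each volume carries, in which order.

A scheme is the ordered per-volume metadata of an STE acquisition: diffusion
weighting b (s/mm^2), encoding type, acquisition position, and a b=0 flag.
The shell order of real protocols is randomised to decorrelate slow scanner
drift from diffusion weighting, and b=0 volumes are interleaved at a fixed
cadence to track that drift; both properties are reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SchemeVolume",
    "AcquisitionScheme",
    "build_scheme",
    "read_scheme",
    "write_scheme",
    "DEFAULT_B_VALUES",
    "DEFAULT_REPEATS",
    "DEFAULT_B0_INTERVAL",
]

#: default STE b-shells, s/mm^2
DEFAULT_B_VALUES = (250, 1500, 3000, 4500, 6000, 7500, 9000, 10500, 12000, 13500, 15000)

#: default per-shell repeats; counts grow with b to balance the SNR loss of
#: stronger weighting (a package default -- protocols vary)
DEFAULT_REPEATS = (2, 2, 3, 3, 4, 4, 5, 6, 7, 8, 9)

#: insert a b=0 volume at every position divisible by this
DEFAULT_B0_INTERVAL = 15


@dataclass(frozen=True)
class SchemeVolume:
    """Metadata of a single acquired volume."""

    b: float  # s/mm^2
    encoding: str
    acq_index: int
    is_b0: bool

    def __post_init__(self):
        if self.b < 0 or not np.isfinite(self.b):
            raise ValueError(f"b must be finite and >= 0, got {self.b}")
        if self.is_b0 and self.b != 0:
            raise ValueError(f"volume flagged b0 has b={self.b}")
        if self.encoding != "STE":
            raise ValueError(f"unsupported encoding {self.encoding!r} (only STE)")


class AcquisitionScheme:
    """Ordered list of :class:`SchemeVolume` with fit-readiness checks."""

    def __init__(self, volumes):
        volumes = list(volumes)
        if not volumes:
            raise ValueError("scheme must contain at least one volume")
        idx = [v.acq_index for v in volumes]
        if len(set(idx)) != len(idx):
            raise ValueError("acq_index values must be unique")
        self.volumes = volumes

    def __len__(self):
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    def __eq__(self, other):
        return isinstance(other, AcquisitionScheme) and self.volumes == other.volumes

    @property
    def b_values(self) -> np.ndarray:
        """Per-volume b in s/mm^2, in acquisition order."""
        return np.array([v.b for v in self.volumes], dtype=float)

    @property
    def acq_indices(self) -> np.ndarray:
        return np.array([v.acq_index for v in self.volumes], dtype=int)

    @property
    def is_b0(self) -> np.ndarray:
        return np.array([v.is_b0 for v in self.volumes], dtype=bool)

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct non-zero b-values."""
        b = self.b_values
        return np.unique(b[b > 0])

    def validate_for_fitting(self, b_low: float, b_high: float) -> None:
        """Check both fit regimes are sampled well enough to be attempted.

        Requires >= 2 distinct non-zero shells at b <= ``b_low`` and >= 2
        distinct shells at b >= ``b_high`` (s/mm^2). Raises ValueError
        naming the missing regime.
        """
        shells = self.shells
        if (shells <= b_low).sum() < 2:
            raise ValueError(
                f"scheme has {(shells <= b_low).sum()} distinct non-zero shells at "
                f"b <= {b_low} s/mm^2; the low-b free-water fit needs at least 2"
            )
        if (shells >= b_high).sum() < 2:
            raise ValueError(
                f"scheme has {(shells >= b_high).sum()} distinct shells at "
                f"b >= {b_high} s/mm^2; the high-b sphere fit needs at least 2"
            )


def build_scheme(
    b_values=DEFAULT_B_VALUES,
    repeats=None,
    b0_interval: int = DEFAULT_B0_INTERVAL,
    order_seed: int = 0,
) -> AcquisitionScheme:
    """Build an STE scheme with randomised shell order and interleaved b0s.

    Parameters
    ----------
    b_values
        Distinct shell b-values in s/mm^2.
    repeats
        Number of acquisitions per shell (same length as ``b_values``).
        Defaults to :data:`DEFAULT_REPEATS` when ``b_values`` is the default
        list, otherwise to one repeat per shell.
    b0_interval
        A b=0 volume occupies every position whose index is a multiple of
        this (so the scheme always opens with a b0). Must be >= 2.
    order_seed
        Seed of the shuffle; the same seed reproduces the same order.
    """
    b_values = list(b_values)
    if repeats is None:
        repeats = list(DEFAULT_REPEATS) if tuple(b_values) == tuple(DEFAULT_B_VALUES) else [1] * len(b_values)
    repeats = list(repeats)
    if len(repeats) != len(b_values):
        raise ValueError(
            f"b_values has {len(b_values)} entries but repeats has {len(repeats)}"
        )
    if any(r < 1 for r in repeats):
        raise ValueError("every shell needs at least one repeat")
    if any(b <= 0 for b in b_values):
        raise ValueError("shell b-values must be positive (b0s are interleaved automatically)")
    if b0_interval < 2:
        raise ValueError("b0_interval must be >= 2")

    weighted = [float(b) for b, r in zip(b_values, repeats) for _ in range(r)]
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(weighted))
    weighted = [weighted[i] for i in order]

    volumes = []
    acq = 0
    it = iter(weighted)
    remaining = len(weighted)
    while remaining > 0:
        if acq % b0_interval == 0:
            volumes.append(SchemeVolume(0.0, "STE", acq, True))
        else:
            volumes.append(SchemeVolume(next(it), "STE", acq, False))
            remaining -= 1
        acq += 1
    return AcquisitionScheme(volumes)


# --- plain-text sidecar I/O -------------------------------------------------
# one row per volume: b  encoding  acq_index  is_b0; '#' lines are comments

def write_scheme(scheme: AcquisitionScheme, path) -> None:
    path = Path(path)
    lines = ["# b_s_per_mm2  encoding  acq_index  is_b0"]
    for v in scheme:
        lines.append(f"{v.b:.6g}  {v.encoding}  {v.acq_index}  {int(v.is_b0)}")
    path.write_text("\n".join(lines) + "\n")


def read_scheme(path) -> AcquisitionScheme:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read scheme file {path}: {exc}") from exc
    volumes = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise IOError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
        b, enc, acq, isb0 = parts
        volumes.append(SchemeVolume(float(b), enc, int(acq), bool(int(isb0))))
    if not volumes:
        raise IOError(f"scheme file {path} contains no volumes")
    return AcquisitionScheme(volumes)
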