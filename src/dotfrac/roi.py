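"""Voxel-inclusion filters and per-lobule/lobe median summaries.

Grey-matter voxels enter the analysis only if the tissue fraction exceeds a
floor (ft > 0.3 by default, trimming CSF partial volume) and their fs and
Ds fall within the per-subject 99th percentile over labelled grey matter
(trimming fit blow-ups). Lobule labels are grouped into the four cerebellar
lobes -- anterior (A), superior posterior (SP), inferior posterior (IP) and
flocculonodular (F) -- and lobe medians are computed over the *pooled*
voxels of their lobules, never as medians of lobule medians. Regions with
fewer than ``min_voxels`` surviving voxels (default 5) are flagged excluded
and carry no value (in practice this removes the tiny flocculonodular
lobe).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import ParameterMaps
from .synthetic import DEFAULT_LOBE_OF_LABEL

__all__ = [
    "LobuleLabelMap",
    "RoiSummary",
    "filter_voxels",
    "summarize",
    "summarize_cohort",
    "group_median_mad",
    "restrict_to_mapping",
    "METRICS",
]

METRICS = ("MD", "fs", "Ds")
_LOBES = ("A", "SP", "IP", "F")
_METRIC_ATTR = {"MD": "md", "fs": "fs", "Ds": "ds"}


@dataclass(frozen=True)
class LobuleLabelMap:
    """Integer lobule label volume plus the lobule -> lobe mapping."""

    labels: np.ndarray
    lobe_of: dict = None

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        lobe_of = dict(self.lobe_of) if self.lobe_of is not None else dict(DEFAULT_LOBE_OF_LABEL)
        present = set(np.unique(labels)) - {0}
        missing = present - set(lobe_of)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from the lobe mapping")
        bad = set(lobe_of.values()) - set(_LOBES)
        if bad:
            raise ValueError(f"unknown lobes {sorted(bad)}; expected {_LOBES}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "lobe_of", lobe_of)

    @classmethod
    def from_csv(cls, labels, mapping_path):
        """Mapping from a 2-column CSV (label, lobe)."""
        table = pd.read_csv(mapping_path, header=None, names=["label", "lobe"],
                            comment="#", skipinitialspace=True)
        return cls(labels, dict(zip(table["label"].astype(int), table["lobe"].str.strip())))


@dataclass(frozen=True)
class RoiSummary:
    """Per-region medians of one subject (long table)."""

    subject: str
    table: pd.DataFrame  # region, kind (lobule|lobe), metric, value, n_voxels, excluded


def restrict_to_mapping(labels, lobe_of=None) -> np.ndarray:
    """Zero out labels absent from the lobe mapping (e.g. WM/CSF classes)."""
    lobe_of = lobe_of if lobe_of is not None else DEFAULT_LOBE_OF_LABEL
    labels = np.asarray(labels)
    return np.where(np.isin(labels, list(lobe_of)), labels, 0)


def filter_voxels(maps: ParameterMaps, label_map: LobuleLabelMap,
                  ft_min: float = 0.3, pct: float = 99.0) -> np.ndarray:
    """Inclusion mask for the labelled grey-matter voxels of one subject.

    A voxel survives if it is labelled, all three metrics are finite,
    ft > ``ft_min``, and both fs and Ds lie at or below the per-subject
    ``pct``-th percentile computed across all labelled voxels *after* the
    ft filter (so CSF-dominated voxels cannot distort the trim point).
    """
    labels = label_map.labels
    if labels.shape != maps.grid:
        raise ValueError(f"label grid {labels.shape} != map grid {maps.grid}")
    labelled = labels > 0
    if not labelled.any():
        raise ValueError("label volume contains no labelled voxels")
    finite = np.isfinite(maps.ft) & np.isfinite(maps.md) & np.isfinite(maps.fs) & np.isfinite(maps.ds)
    base = labelled & finite & (maps.ft > ft_min)
    if not base.any():
        return base
    fs_cut = np.percentile(maps.fs[base], pct)
    ds_cut = np.percentile(maps.ds[base], pct)
    return base & (maps.fs <= fs_cut) & (maps.ds <= ds_cut)


def summarize(maps: ParameterMaps, label_map: LobuleLabelMap, mask: np.ndarray,
              min_voxels: int = 5, subject: str = "subject") -> RoiSummary:
    """Median MD/fs/Ds per lobule and per lobe over the masked voxels.

    Lobe values pool the voxels of all constituent lobules before taking
    the median. Regions with fewer than ``min_voxels`` masked voxels are
    flagged excluded and carry NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("inclusion mask is empty")
    labels = label_map.labels
    rows = []

    def add_region(region, kind, sel):
        n = int(sel.sum())
        excluded = n < min_voxels
        for metric in METRICS:
            vals = getattr(maps, _METRIC_ATTR[metric])[sel]
            rows.append({
                "region": region, "kind": kind, "metric": metric,
                "value": np.nan if excluded else float(np.median(vals)),
                "n_voxels": n, "excluded": excluded,
            })

    lobe_sel = {lobe: np.zeros(labels.shape, dtype=bool) for lobe in _LOBES}
    for label in sorted(set(label_map.lobe_of)):
        sel = mask & (labels == label)
        add_region(str(label), "lobule", sel)
        lobe_sel[label_map.lobe_of[label]] |= sel
    for lobe in _LOBES:
        if lobe in set(label_map.lobe_of.values()):
            add_region(lobe, "lobe", lobe_sel[lobe])
    add_region("cerebellum", "overall", mask & (labels > 0))
    return RoiSummary(subject, pd.DataFrame(rows))


def summarize_cohort(summaries: list[RoiSummary], covariates: pd.DataFrame) -> pd.DataFrame:
    """Tidy long cohort table: one row per (subject, region, metric).

    ``covariates`` must contain ``subject`` and ``group`` columns; extra
    columns (e.g. cerebellar volume) are carried along. Region sets must
    agree across subjects and subject ids must be unique.
    """
    subjects = [s.subject for s in summaries]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicated subject ids in cohort")
    cov = covariates.set_index("subject")
    if cov.index.duplicated().any():
        raise ValueError("duplicated subject ids in covariates table")
    ref_regions = None
    frames = []
    for s in summaries:
        regions = frozenset(zip(s.table["region"], s.table["metric"]))
        if ref_regions is None:
            ref_regions = regions
        elif regions != ref_regions:
            raise ValueError(f"subject {s.subject} has a mismatched region set")
        t = s.table.copy()
        t.insert(0, "subject", s.subject)
        for col in cov.columns:
            t[col] = cov.loc[s.subject, col]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def group_median_mad(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, region, metric) median and median absolute deviation.

    The Median (MAD) presentation conventional for non-normal ROI metrics;
    excluded regions are dropped before aggregation.
    """
    t = cohort_table[~cohort_table["excluded"]]

    def mad(x):
        x = np.asarray(x, dtype=float)
        return float(np.median(np.abs(x - np.median(x))))

    out = (
        t.groupby(["group", "region", "kind", "metric"])["value"]
        .agg(median="median", mad=mad, n="count")
        .reset_index()
    )
    return out
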