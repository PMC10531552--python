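"""Per-voxel analysis table: outlier filtering, volumes, summary statistics.

A :class:`VoxelTable` wraps a pandas DataFrame with at least ``adc`` and
``suv`` columns (optionally ``patient_id``, ``timepoint``, ``tissue_group``,
``cluster`` and voxel indices) plus the grid spacing needed to convert voxel
counts into volumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "post")

#: clinical ADC outlier cutoff, 1e-6 mm^2/s; records at or below are excluded
ADC_OUTLIER = 50.0


class VoxelVolume(NamedTuple):
    mm3: float
    ml: float


def voxel_volume(spacing: tuple[float, float, float]) -> VoxelVolume:
    """Single-voxel volume from grid spacing: product in mm^3, and in mL."""
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    mm3 = float(spacing[0]) * float(spacing[1]) * float(spacing[2])
    return VoxelVolume(mm3=mm3, ml=mm3 * 1e-3)


@dataclass
class VoxelTable:
    """Flat per-voxel record set consumed by every downstream stage."""

    df: pd.DataFrame
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for col in ("adc", "suv"):
            if col not in self.df.columns:
                raise ValueError(f"VoxelTable requires an {col!r} column")
        if "timepoint" in self.df.columns:
            bad = set(self.df["timepoint"].dropna().unique()) - set(TIMEPOINTS)
            if bad:
                raise ValueError(f"unknown timepoint values {sorted(bad)}; allowed {TIMEPOINTS}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_voxels(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "VoxelTable":
        return replace(self, df=df)


@dataclass(frozen=True)
class SummaryStats:
    """n, volume and distributional summaries of ADC and SUV."""

    n_voxels: int
    volume_ml: float
    adc_mean: float
    adc_median: float
    adc_p5: float
    adc_p95: float
    suv_mean: float
    suv_median: float
    suv_p5: float
    suv_p95: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_outliers(table: VoxelTable, adc_outlier: float = ADC_OUTLIER) -> VoxelTable:
    """Drop records with ADC <= ``adc_outlier``; survivor order is preserved."""
    keep = table.df["adc"] > adc_outlier
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_outliers: removed %d of %d records (ADC <= %g)",
                    n_removed, len(table), adc_outlier)
    out = table.df.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("filter_outliers: no records survive the outlier filter", stacklevel=2)
    return table.with_df(out)


def total_volume(table: VoxelTable) -> float:
    """Total volume in mL: record count times the single-voxel volume."""
    if table.spacing is None:
        raise ValueError("table carries no grid spacing; cannot compute volume")
    return table.n_voxels * voxel_volume(table.spacing).ml


def summarize(table: VoxelTable) -> SummaryStats:
    """Mean, median and 5th/95th percentiles of ADC and SUV.

    Percentiles use linear interpolation between order statistics.
    """
    if table.n_voxels == 0:
        raise ValueError("cannot summarize an empty table")
    adc = table.df["adc"].to_numpy(dtype=float)
    suv = table.df["suv"].to_numpy(dtype=float)
    vol = total_volume(table) if table.spacing is not None else float("nan")
    return SummaryStats(
        n_voxels=table.n_voxels,
        volume_ml=vol,
        adc_mean=float(np.mean(adc)),
        adc_median=float(np.median(adc)),
        adc_p5=float(np.percentile(adc, 5)),
        adc_p95=float(np.percentile(adc, 95)),
        suv_mean=float(np.mean(suv)),
        suv_median=float(np.median(suv)),
        suv_p5=float(np.percentile(suv, 5)),
        suv_p95=float(np.percentile(suv, 95)),
    )


def read_table(path, spacing=None) -> VoxelTable:
    """Load a voxel table from CSV or parquet."""
    path = str(path)
    df = pd.read_parquet(path) if path.endswith(".parquet") else pd.read_csv(path)
    return VoxelTable(df, spacing=spacing)


def write_table(table: VoxelTable, path) -> None:
    path = str(path)
    if path.endswith(".parquet"):
        table.df.to_parquet(path, index=False)
    else:
        table.df.to_csv(path, index=False)
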