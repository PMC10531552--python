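"""Fixed-threshold virtual tissue groups and their pre/post dynamics.

The quadrant rule on the (ADC, SUV) plane:

* ``vital``      — SUV > suv_cut  and ADC < adc_cut (high uptake, restricted diffusion)
* ``low_vital``  — SUV < suv_cut  and ADC > adc_cut
* ``equivocal``  — everything else, including exact threshold equality

Every retained voxel gets exactly one label (the rule is a partition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .voxels import VoxelTable, voxel_volume

GROUPS = ("vital", "low_vital", "equivocal")


@dataclass(frozen=True)
class TissueThresholds:
    """Clinical cutoffs separating vital from low-vital tissue."""

    suv_cut: float = 2.5
    adc_cut: float = 1250.0  # 1e-6 mm^2/s
    adc_outlier: float = 50.0  # 1e-6 mm^2/s

    def __post_init__(self) -> None:
        if min(self.suv_cut, self.adc_cut, self.adc_outlier) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.adc_outlier >= self.adc_cut:
            raise ValueError("adc_outlier must be below adc_cut")


@dataclass(frozen=True)
class GroupProportions:
    """Per-group counts, volumes and fractions of the total."""

    counts: dict[str, int]
    fractions: dict[str, float]
    volume_ml: dict[str, float]
    thresholds: TissueThresholds = field(default_factory=TissueThresholds)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {total}")


def classify_voxel(adc: float, suv: float, thresholds: TissueThresholds | None = None) -> str:
    """Classify a single voxel; ADC must already be above the outlier cutoff."""
    thresholds = thresholds or TissueThresholds()
    if adc <= thresholds.adc_outlier:
        raise ValueError(
            f"ADC {adc} at or below outlier cutoff {thresholds.adc_outlier}; filter upstream"
        )
    if suv > thresholds.suv_cut and adc < thresholds.adc_cut:
        return "vital"
    if suv < thresholds.suv_cut and adc > thresholds.adc_cut:
        return "low_vital"
    return "equivocal"


def classify_table(table: VoxelTable, thresholds: TissueThresholds | None = None) -> VoxelTable:
    """Vectorized quadrant classification; adds a ``tissue_group`` column."""
    thresholds = thresholds or TissueThresholds()
    adc = table.df["adc"].to_numpy(dtype=float)
    suv = table.df["suv"].to_numpy(dtype=float)
    if (adc <= thresholds.adc_outlier).any():
        raise ValueError("table contains ADC values at or below the outlier cutoff; "
                         "apply filter_outliers first")
    labels = np.full(len(adc), "equivocal", dtype=object)
    labels[(suv > thresholds.suv_cut) & (adc < thresholds.adc_cut)] = "vital"
    labels[(suv < thresholds.suv_cut) & (adc > thresholds.adc_cut)] = "low_vital"
    df = table.df.copy()
    df["tissue_group"] = labels
    return table.with_df(df)


def group_proportions(table: VoxelTable, thresholds: TissueThresholds | None = None) -> GroupProportions:
    """Counts, volumes and fractions per tissue group (classifying if needed)."""
    thresholds = thresholds or TissueThresholds()
    if table.n_voxels == 0:
        raise ValueError("cannot compute proportions of an empty table")
    if "tissue_group" not in table.df.columns:
        table = classify_table(table, thresholds)
    counts = {g: int((table.df["tissue_group"] == g).sum()) for g in GROUPS}
    n = table.n_voxels
    vvol = voxel_volume(table.spacing).ml if table.spacing is not None else float("nan")
    return GroupProportions(
        counts=counts,
        fractions={g: counts[g] / n for g in GROUPS},
        volume_ml={g: counts[g] * vvol for g in GROUPS},
        thresholds=thresholds,
    )


def compare_timepoints(
    pre: GroupProportions,
    post: GroupProportions,
    dead_band: float = 0.0,
) -> dict[str, dict]:
    """Signed per-group change and a direction label with a configurable dead-band."""
    if pre.thresholds != post.thresholds:
        raise ValueError("pre and post proportions were computed with different thresholds")
    out = {}
    for g in GROUPS:
        delta = post.fractions[g] - pre.fractions[g]
        if delta > dead_band:
            label = "increase"
        elif delta < -dead_band:
            label = "decrease"
        else:
            label = "unchanged"
        out[g] = {"delta": delta, "direction": label}
    return out
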