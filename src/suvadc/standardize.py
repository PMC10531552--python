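"""Size standardization to a fixed voxel count and pooled z-normalization.

``standardize_size`` reads "reduced or extrapolated to the same volume of N
voxels" as: uniform subsampling without replacement when the tumor is larger
than N, bootstrap resampling with replacement when smaller, identity when
equal.  The bootstrap preserves the empirical distribution without inventing
values.

``znormalize`` uses the population (divide-by-n) standard deviation so the
unit-variance postcondition is exact.
"""

from __future__ import annotations

import numpy as np

from .voxels import VoxelTable


def standardize_size(
    table: VoxelTable,
    n_target: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> VoxelTable:
    """Return a table with exactly ``n_target`` records, seeded and reproducible."""
    if table.n_voxels == 0:
        raise ValueError("cannot standardize an empty table")
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    n = table.n_voxels
    if n == n_target:
        return table.with_df(table.df.reset_index(drop=True))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=n_target, replace=n < n_target)
    return table.with_df(table.df.iloc[idx].reset_index(drop=True))


def znormalize(values) -> tuple[np.ndarray, float, float]:
    """z-score a pooled value list; returns (normalized, mean, sd).

    Uses the population sd.  Refuses degenerate input (n < 2 or zero variance).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values to normalize, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population convention (ddof=0)
    if sd == 0.0:
        raise ValueError("zero variance: cannot z-normalize a constant input")
    return (x - mean) / sd, mean, sd


def znormalize_table(table: VoxelTable) -> tuple[VoxelTable, dict]:
    """Add ``adc_norm``/``suv_norm`` columns, pooling across all rows.

    Returns the augmented table and the (mean, sd) constants per channel so
    the transform can be inverted exactly.
    """
    adc_n, adc_mean, adc_sd = znormalize(table.df["adc"].to_numpy())
    suv_n, suv_mean, suv_sd = znormalize(table.df["suv"].to_numpy())
    df = table.df.copy()
    df["adc_norm"] = adc_n
    df["suv_norm"] = suv_n
    constants = {
        "adc": {"mean": adc_mean, "sd": adc_sd},
        "suv": {"mean": suv_mean, "sd": suv_sd},
    }
    return table.with_df(df), constants
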