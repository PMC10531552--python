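"""Scalar-volume I/O, grid resampling and masked voxel extraction.

Conventions (fixed once, used everywhere):

* arrays are indexed ``(x, y, z)`` in NIfTI header order, 0-based;
* world coordinates follow the NIfTI affine; the volumes produced here are
  axis-aligned, so the affine is ``diag(spacing)`` plus an origin translation;
* the canonical ADC unit is 1e-6 mm^2/s, so the clinical cutoff is the
  number 1250; readers auto-detect SI inputs (mm^2/s) by magnitude and
  convert;
* values that fall outside a source volume during resampling are marked
  missing (NaN), never extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

Quantity = Literal["suv", "adc"]

#: below this median magnitude an ADC volume is assumed to be in mm^2/s
_ADC_SI_MEDIAN_CUTOFF = 0.1
_ADC_SI_FACTOR = 1e6


@dataclass(frozen=True)
class GridSpec:
    """Target sampling grid: shape, spacing (mm) and world origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")


@dataclass
class ScalarVolume:
    """A 3D grid of one physical quantity with spacing/origin metadata.

    Parameters
    ----------
    values
        3D float array, indexed (x, y, z). Missing values are NaN.
    spacing
        Voxel edge lengths in mm per axis; strictly positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    quantity
        ``"suv"`` (unitless) or ``"adc"`` (1e-6 mm^2/s); fixed at construction.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: Quantity = "suv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.quantity not in ("suv", "adc"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)


@dataclass
class VOIMask:
    """Binary tumor mask on the MR analysis grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, quantity: Quantity) -> ScalarVolume:
    """Read a NIfTI-1 file into a :class:`ScalarVolume`.

    ADC volumes stored in SI units (mm^2/s, values around 1e-3) are detected
    by their median magnitude and converted to the canonical 1e-6 mm^2/s.
    """
    if quantity not in ("suv", "adc"):
        raise ValueError(f"unknown quantity {quantity!r}")
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={values.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    if quantity == "adc":
        finite = values[np.isfinite(values) & (values > 0)]
        if finite.size and float(np.median(finite)) < _ADC_SI_MEDIAN_CUTOFF:
            logger.info("%s: ADC magnitude suggests mm^2/s; converting x%g", path, _ADC_SI_FACTOR)
            values = values * _ADC_SI_FACTOR
    return ScalarVolume(values, spacing, origin, quantity)


def write_volume(volume: ScalarVolume | VOIMask, path: str | Path, dtype=None) -> Path:
    """Write a volume or mask as NIfTI-1 with spacing/origin in the header."""
    path = Path(path)
    values = volume.values
    if isinstance(volume, VOIMask):
        values = values.astype(np.uint8)
    elif dtype is not None:
        values = values.astype(dtype)
    img = nib.Nifti1Image(values, _affine_from(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> VOIMask:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got ndim={values.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VOIMask(values > 0, spacing, origin, provenance=str(path))


def resample_to_grid(
    volume: ScalarVolume,
    target: GridSpec,
    interpolation: Literal["trilinear", "nearest"] = "trilinear",
) -> ScalarVolume:
    """Resample ``volume`` onto ``target`` in world coordinates.

    Trilinear interpolation for continuous fields, nearest-neighbour for
    categorical ones.  Target voxels whose centers fall outside the source
    extent come back as NaN.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0

    src_spacing = np.asarray(volume.spacing)
    src_origin = np.asarray(volume.origin)
    tgt_spacing = np.asarray(target.spacing)
    tgt_origin = np.asarray(target.origin)

    idx = np.indices(target.shape, dtype=float)  # (3, nx, ny, nz)
    world = idx * tgt_spacing[:, None, None, None] + tgt_origin[:, None, None, None]
    src_idx = (world - src_origin[:, None, None, None]) / src_spacing[:, None, None, None]

    # reject before interpolating: centers outside [0, n-1] have no support
    upper = np.array(volume.shape, dtype=float) - 1.0
    eps = 1e-9
    outside = np.zeros(target.shape, dtype=bool)
    for ax in range(3):
        outside |= (src_idx[ax] < -eps) | (src_idx[ax] > upper[ax] + eps)
    if outside.all():
        raise ValueError("no overlap between source and target grids")

    out = map_coordinates(volume.values, src_idx, order=order, mode="nearest")
    out[outside] = np.nan
    return ScalarVolume(out, target.spacing, target.origin, volume.quantity)


def extract_masked_pairs(
    suv_on_mr: ScalarVolume,
    adc: ScalarVolume,
    mask: VOIMask,
) -> pd.DataFrame:
    """One (adc, suv, i, j, k) record per foreground mask voxel.

    All three inputs must share the MR grid.  Records where either value is
    missing are dropped and the drop count logged.
    """
    if suv_on_mr.shape != adc.shape or adc.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: suv {suv_on_mr.shape}, adc {adc.shape}, mask {mask.shape}"
        )
    if mask.n_foreground == 0:
        raise ValueError("empty mask: no foreground voxels")

    i, j, k = np.nonzero(mask.values)
    adc_v = adc.values[i, j, k]
    suv_v = suv_on_mr.values[i, j, k]
    keep = np.isfinite(adc_v) & np.isfinite(suv_v)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("extract_masked_pairs: dropped %d voxels with missing values", n_drop)
    df = pd.DataFrame(
        {
            "adc": adc_v[keep],
            "suv": suv_v[keep],
            "i": i[keep].astype(np.int64),
            "j": j[keep].astype(np.int64),
            "k": k[keep].astype(np.int64),
        }
    )
    logger.info("extract_masked_pairs: %d records from %d mask voxels", len(df), mask.n_foreground)
    return df
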