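"""Synthetic tumor phantoms: paired SUV/ADC volumes with known compartments.

Each phantom is an axis-aligned ellipsoidal tumor on the MR analysis grid.
Mask voxels are partitioned into spatially contiguous blobs (nearest seed
point in world coordinates) and blobs are assigned to three latent tissue
compartments — vital, equivocal, low-vital — so the empirical compartment
fractions track the configured ones.  Each voxel then draws an (ADC, SUV)
pair from its compartment's bivariate Gaussian, truncated to physical
nonnegativity by rejection sampling; the vital compartment carries a
configurable negative ADC-SUV coupling.  The SUV channel is additionally
emitted on a coarser PET grid by local averaging, mimicking the lower PET
resolution.

Therapy-course transforms shrink the mask and redraw compartments so that a
"response" phantom loses essentially all vital tissue (mean ADC up, mean SUV
down) while a "progression" phantom gains vital tissue (mean ADC down, mean
SUV up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree

from .volumes import GridSpec, ScalarVolume, VOIMask, read_mask, read_volume, resample_to_grid, write_volume

COMPARTMENTS = ("vital", "equivocal", "low_vital")
_LABEL_CODES = {"vital": 1, "equivocal": 2, "low_vital": 3}

TherapyMode = Literal["response", "progression"]

def _normalized(fr: tuple[float, ...]) -> tuple[float, ...]:
    s = sum(fr)
    return tuple(f / s for f in fr)


#: post-therapy compartment fractions (vital, equivocal, low_vital);
#: the response triple is renormalized because the printed percentages sum to 100.03
RESPONSE_FRACTIONS = _normalized((0.0003, 0.343, 0.657))
PROGRESSION_FRACTIONS = (0.418, 0.333, 0.249)
#: default total-volume factors applied to the tumor mask
RESPONSE_VOLUME_FACTOR = 0.2
PROGRESSION_VOLUME_FACTOR = 0.5


@dataclass(frozen=True)
class CompartmentEmission:
    """Bivariate (ADC, SUV) emission distribution of one tissue compartment."""

    mean_adc: float
    mean_suv: float
    sd_adc: float = 150.0
    sd_suv: float = 0.7
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_adc <= 0 or self.sd_suv <= 0:
            raise ValueError("emission standard deviations must be positive")
        if not -1 < self.rho < 1:
            raise ValueError(f"correlation must be in (-1, 1), got {self.rho}")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_adc, self.mean_suv])

    @property
    def cov(self) -> np.ndarray:
        off = self.rho * self.sd_adc * self.sd_suv
        return np.array([[self.sd_adc**2, off], [off, self.sd_suv**2]])


def _default_compartments(vital_coupling: float) -> dict[str, CompartmentEmission]:
    # means straddle the clinical cutoffs (SUV 2.5, ADC 1250) by design,
    # each sitting well inside its quadrant so threshold recovery is clean
    return {
        "vital": CompartmentEmission(850.0, 4.0, rho=vital_coupling),
        "equivocal": CompartmentEmission(900.0, 1.0),
        "low_vital": CompartmentEmission(1700.0, 1.2),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to generate one reproducible phantom.

    ``compartment_fractions`` follow the order (vital, equivocal, low_vital)
    and must sum to 1.  ``ellipsoid_scale`` sets the tumor semi-axes as a
    fraction of the half-grid; ``n_blobs`` controls the spatial granularity
    of the compartments (free parameter, not an inference target).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    mr_spacing: tuple[float, float, float] = (0.7, 0.7, 5.0)
    pet_spacing: tuple[float, float, float] = (2.8, 2.8, 2.0)
    compartment_fractions: tuple[float, float, float] = (0.263, 0.379, 0.358)
    compartment_params: dict[str, CompartmentEmission] | None = None
    vital_coupling: float = -0.4
    noise_sd: tuple[float, float] = (20.0, 0.05)  # additive (ADC, SUV) noise
    ellipsoid_scale: float = 0.9
    n_blobs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.compartment_fractions
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError(f"compartment fractions must sum to 1, got {sum(fr)}")
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("compartment fractions must lie in [0, 1]")
        if any(s <= 0 for s in self.mr_spacing) or any(s <= 0 for s in self.pet_spacing):
            raise ValueError("spacings must be strictly positive")
        if self.vital_coupling >= 0:
            raise ValueError("vital_coupling must be negative")
        params = self.params()
        if not (params["vital"].mean_suv > 2.5 and params["vital"].mean_adc < 1250):
            raise ValueError("vital compartment mean must have SUV > 2.5 and ADC < 1250")
        if not (params["low_vital"].mean_suv < 2.5 and params["low_vital"].mean_adc > 1250):
            raise ValueError("low-vital compartment mean must have SUV < 2.5 and ADC > 1250")
        if self.ellipsoid_scale <= 0 or self.ellipsoid_scale > 1:
            raise ValueError("ellipsoid_scale must be in (0, 1]")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")

    def params(self) -> dict[str, CompartmentEmission]:
        if self.compartment_params is not None:
            return self.compartment_params
        return _default_compartments(self.vital_coupling)


@dataclass
class Phantom:
    """Generated phantom: volumes, mask, ground-truth labels and config."""

    suv_pet: ScalarVolume
    adc: ScalarVolume
    mask: VOIMask
    labels: np.ndarray  # int codes on the MR grid; 0 outside the mask
    config: PhantomConfig
    suv_mr: ScalarVolume | None = None  # noise-level truth before PET degradation
    timepoint: str = "baseline"

    def truth_fractions(self) -> dict[str, float]:
        inside = self.labels[self.mask.values]
        n = inside.size
        return {name: float((inside == code).sum()) / n for name, code in _LABEL_CODES.items()}


def _ellipsoid_mask(shape, scale: float) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = scale * np.asarray(shape) / 2.0
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[ax] - center[ax]) / semi[ax]) ** 2 for ax in range(3))
    return r2 <= 1.0


def _blob_partition(coords_mm: np.ndarray, n_blobs: int, rng: np.random.Generator) -> np.ndarray:
    """Nearest-seed-point partition of mask voxels into contiguous blobs."""
    n = coords_mm.shape[0]
    n_blobs = min(n_blobs, n)
    seeds = coords_mm[rng.choice(n, size=n_blobs, replace=False)]
    _, blob_of = cKDTree(seeds).query(coords_mm)
    return blob_of


def _assign_blobs(blob_of: np.ndarray, fractions, rng: np.random.Generator) -> np.ndarray:
    """Greedily assign blobs to compartments to track the target fractions.

    Blobs are taken largest-first and handed to the compartment with the
    largest remaining voxel deficit, so empirical fractions land within about
    one blob of the targets.
    """
    n = blob_of.size
    blob_ids, blob_sizes = np.unique(blob_of, return_counts=True)
    order = np.argsort(blob_sizes)[::-1]
    deficit = np.asarray(fractions, dtype=float) * n
    comp_of_blob = np.empty(blob_ids.size, dtype=np.int64)
    for b in order:
        c = int(np.argmax(deficit))
        comp_of_blob[b] = c
        deficit[c] -= blob_sizes[b]
    return comp_of_blob[blob_of]


def _draw_truncated(rng: np.random.Generator, emission: CompartmentEmission,
                    noise_sd, n: int) -> np.ndarray:
    """Draw n (ADC, SUV) pairs with noise, rejecting ADC <= 0 or SUV < 0."""
    out = np.empty((n, 2))
    need = np.arange(n)
    for _ in range(1000):
        draws = rng.multivariate_normal(emission.mean, emission.cov, size=need.size)
        draws[:, 0] += rng.normal(0.0, noise_sd[0], size=need.size)
        draws[:, 1] += rng.normal(0.0, noise_sd[1], size=need.size)
        ok = (draws[:, 0] > 0) & (draws[:, 1] >= 0)
        out[need[ok]] = draws[ok]
        need = need[~ok]
        if need.size == 0:
            return out
    raise RuntimeError("rejection sampling failed to converge; check emission parameters")


def _pet_grid(mr_grid: GridSpec, pet_spacing) -> GridSpec:
    extent = np.asarray(mr_grid.shape) * np.asarray(mr_grid.spacing)
    shape = tuple(int(np.ceil(e / s)) for e, s in zip(extent, pet_spacing))
    return GridSpec(shape, tuple(pet_spacing), mr_grid.origin)


def generate_phantom(config: PhantomConfig, timepoint: str = "baseline") -> Phantom:
    """Generate one phantom; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    mr_spacing = tuple(config.mr_spacing)

    mask_arr = _ellipsoid_mask(shape, config.ellipsoid_scale)
    n_mask = int(mask_arr.sum())
    if n_mask == 0:
        raise ValueError("mask is empty; enlarge the grid or ellipsoid_scale")
    if n_mask < 0.05 * np.prod(shape):
        raise ValueError("tumor mask occupies less than 5% of the grid")

    vox_idx = np.argwhere(mask_arr)
    coords_mm = vox_idx * np.asarray(mr_spacing)
    blob_of = _blob_partition(coords_mm, config.n_blobs, rng)
    comp_of = _assign_blobs(blob_of, config.compartment_fractions, rng)

    labels = np.zeros(shape, dtype=np.int16)
    labels[tuple(vox_idx.T)] = comp_of + 1  # codes 1..3 in COMPARTMENTS order

    params = config.params()
    adc_arr = np.empty(shape)
    suv_arr = np.empty(shape)
    # low-uptake, high-diffusion background outside the tumor
    n_bg = int(np.prod(shape)) - n_mask
    bg = ~mask_arr
    adc_arr[bg] = np.maximum(rng.normal(2200.0, 100.0, size=n_bg), 1.0)
    suv_arr[bg] = np.maximum(rng.normal(0.3, 0.05, size=n_bg), 0.0)
    for ci, name in enumerate(COMPARTMENTS):
        sel = comp_of == ci
        if not sel.any():
            continue
        pairs = _draw_truncated(rng, params[name], config.noise_sd, int(sel.sum()))
        ijk = tuple(vox_idx[sel].T)
        adc_arr[ijk] = pairs[:, 0]
        suv_arr[ijk] = pairs[:, 1]

    adc = ScalarVolume(adc_arr, mr_spacing, quantity="adc")
    suv_mr = ScalarVolume(suv_arr, mr_spacing, quantity="suv")
    mask = VOIMask(mask_arr, mr_spacing, provenance=f"phantom seed={config.seed}")

    # PET emission: average over the in-plane PET footprint, then sample the
    # coarser grid (the PET point-spread surrogate)
    win = tuple(max(1, int(round(p / m))) for p, m in zip(config.pet_spacing, mr_spacing))
    blurred = ScalarVolume(uniform_filter(suv_arr, size=win, mode="nearest"),
                           mr_spacing, quantity="suv")
    pet = resample_to_grid(blurred, _pet_grid(mask.grid(), config.pet_spacing), "trilinear")
    pet.values[~np.isfinite(pet.values)] = 0.3

    return Phantom(suv_pet=pet, adc=adc, mask=mask, labels=labels,
                   config=config, suv_mr=suv_mr, timepoint=timepoint)


def _shift_params(params: dict[str, CompartmentEmission], d_adc: float, d_suv: float):
    out = {}
    for name, em in params.items():
        out[name] = replace(em,
                            mean_adc=max(em.mean_adc + d_adc, 100.0),
                            mean_suv=max(em.mean_suv + d_suv, 0.1))
    return out


def apply_therapy_course(
    phantom: Phantom,
    mode: TherapyMode,
    volume_factor: float | None = None,
    fractions: tuple[float, float, float] | None = None,
    adc_shift: float | None = None,
    suv_shift: float | None = None,
) -> Phantom:
    """Derive the post-therapy phantom from a baseline one.

    Response shrinks the tumor (default volume factor 0.2), removes vital
    tissue and shifts emissions so mean ADC rises and mean SUV falls;
    progression keeps more volume (default 0.5) and moves both the other way.
    """
    if mode == "response":
        volume_factor = RESPONSE_VOLUME_FACTOR if volume_factor is None else volume_factor
        fractions = RESPONSE_FRACTIONS if fractions is None else fractions
        adc_shift = 100.0 if adc_shift is None else adc_shift
        suv_shift = -0.3 if suv_shift is None else suv_shift
    elif mode == "progression":
        volume_factor = PROGRESSION_VOLUME_FACTOR if volume_factor is None else volume_factor
        fractions = PROGRESSION_FRACTIONS if fractions is None else fractions
        adc_shift = -100.0 if adc_shift is None else adc_shift
        suv_shift = 0.3 if suv_shift is None else suv_shift
    else:
        raise ValueError(f"unknown therapy mode {mode!r}")

    base = phantom.config
    vital = base.params()["vital"]
    # keep every compartment mean well inside its quadrant after the shift,
    # so post-therapy threshold recovery stays meaningful
    shifted = _shift_params(base.params(), adc_shift, suv_shift)
    shifted["vital"] = replace(shifted["vital"],
                               mean_adc=min(shifted["vital"].mean_adc, 1100.0),
                               mean_suv=max(shifted["vital"].mean_suv, 2.8),
                               rho=vital.rho)
    shifted["equivocal"] = replace(shifted["equivocal"],
                                   mean_adc=min(shifted["equivocal"].mean_adc, 1100.0),
                                   mean_suv=min(shifted["equivocal"].mean_suv, 2.2))
    shifted["low_vital"] = replace(shifted["low_vital"],
                                   mean_adc=max(shifted["low_vital"].mean_adc, 1400.0),
                                   mean_suv=min(shifted["low_vital"].mean_suv, 2.2))
    post_config = replace(
        base,
        compartment_fractions=tuple(fractions),
        compartment_params=shifted,
        ellipsoid_scale=min(1.0, base.ellipsoid_scale * volume_factor ** (1.0 / 3.0)),
        seed=base.seed + 10_000,
    )
    return generate_phantom(post_config, timepoint="post")


def write_phantom(phantom: Phantom, directory: str | Path) -> dict[str, Path]:
    """Write suv/adc/mask/labels as NIfTI-1; round-trips bit-exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "suv": write_volume(phantom.suv_pet, directory / "suv.nii.gz"),
        "adc": write_volume(phantom.adc, directory / "adc.nii.gz"),
        "mask": write_volume(phantom.mask, directory / "mask.nii.gz"),
    }
    labels_vol = ScalarVolume(phantom.labels.astype(float), phantom.adc.spacing, quantity="suv")
    import nibabel as nib

    img = nib.Nifti1Image(phantom.labels.astype(np.int16), labels_vol.affine)
    img.header.set_zooms(phantom.adc.spacing)
    label_path = directory / "labels.nii.gz"
    nib.save(img, str(label_path))
    paths["labels"] = label_path
    return paths


def read_phantom(directory: str | Path, config: PhantomConfig | None = None) -> Phantom:
    """Read a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    import nibabel as nib

    suv = read_volume(directory / "suv.nii.gz", "suv")
    adc = read_volume(directory / "adc.nii.gz", "adc")
    mask = read_mask(directory / "mask.nii.gz")
    labels = np.asarray(nib.load(str(directory / "labels.nii.gz")).dataobj).astype(np.int16)
    return Phantom(suv_pet=suv, adc=adc, mask=mask, labels=labels,
                   config=config or PhantomConfig())
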