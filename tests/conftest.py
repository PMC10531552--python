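import numpy as np
import pytest

from suvadc import PhantomConfig, generate_phantom
from suvadc.pipeline import table_from_phantom
from suvadc.volumes import ScalarVolume, VOIMask, extract_masked_pairs
from suvadc.voxels import VoxelTable


@pytest.fixture(scope="session")
def big_phantom():
    """Baseline phantom with ~1e5 mask voxels (slow; shared across tests)."""
    config = PhantomConfig(grid_shape=(104, 104, 26), seed=11)
    return generate_phantom(config)


@pytest.fixture(scope="session")
def small_phantom():
    config = PhantomConfig(grid_shape=(40, 40, 12), seed=5)
    return generate_phantom(config)


@pytest.fixture(scope="session")
def big_truth_table(big_phantom):
    """Voxel table built from the noise-level MR truth (no PET degradation)."""
    df = extract_masked_pairs(big_phantom.suv_mr, big_phantom.adc, big_phantom.mask)
    codes = big_phantom.labels[df["i"], df["j"], df["k"]]
    df = df.copy()
    df["truth"] = np.array(["", "vital", "equivocal", "low_vital"], dtype=object)[codes]
    return VoxelTable(df, spacing=big_phantom.mask.spacing)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(adc, suv, spacing=(0.7, 0.7, 5.0), **extra):
    import pandas as pd

    df = pd.DataFrame({"adc": np.asarray(adc, dtype=float),
                       "suv": np.asarray(suv, dtype=float), **extra})
    return VoxelTable(df, spacing=spacing)
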