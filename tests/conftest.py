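import numpy as np
import pytest

from vascupet import PhantomSpec, VoiMask, VolumeGrid


@pytest.fixture
def clean_spec() -> PhantomSpec:
    """Noise-free, blur-free phantom: every region value has a closed form."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        voxel_size_mm=1.4,
        blood_activity=10000.0,
        vascular_fraction=0.1,
        noise="none",
        psf_sigma_mm=0.0,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220227)


def make_volume(values, voxel_size_mm=1.0, unit="Bq_per_mL") -> VolumeGrid:
    return VolumeGrid(np.asarray(values, dtype=float), voxel_size_mm, unit)


def make_mask(values, voxel_size_mm=1.0) -> VoiMask:
    return VoiMask(np.asarray(values), voxel_size_mm)
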