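import numpy as np
import pytest

from rapidvol import GeneratorConfig, TissueMapSet


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def tiny_config():
    """Small, fast configuration for structural tests."""
    return GeneratorConfig(
        n_participants=12,
        n_retest=4,
        grid_shape=(10, 10, 8),
        voxel_dims=(4.0, 4.0, 6.0),
        fov_drop_slices=1,
        seed=42,
    )


@pytest.fixture
def noise_free_config():
    """Configuration in which standard and rapid acquisitions coincide."""
    return GeneratorConfig(
        n_participants=8,
        n_retest=3,
        grid_shape=(10, 10, 8),
        cross_sequence_corr_target={"GM": 1.0, "WM": 1.0, "CSF": 1.0},
        standard_noise_sd={"GM": 0.0, "WM": 0.0, "CSF": 0.0},
        retest_noise_sd=0.0,
        fov_drop_slices=0,
        smoothing_fwhm=0.0,
        seed=5,
    )


def make_mapset(values, sequence="standard", tissue="GM", voxel_dims=(4.0, 4.0, 6.0),
                fov_mask=None, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"sub-{i + 1:04d}" for i in range(values.shape[0])]
    return TissueMapSet(
        values=values,
        participant_ids=ids,
        tissue_class=tissue,
        sequence_label=sequence,
        voxel_dims=voxel_dims,
        fov_mask=fov_mask,
    )
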