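import numpy as np
import pytest

from svrlsm.lesions import LesionMatrix, compress_patches
from svrlsm.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-featured synthetic cohort (30 subjects)."""
    return simulate_cohort(SimConfig(seed=42, n_subjects=30))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 94-subject cohort used for end-to-end checks."""
    return simulate_cohort(SimConfig(seed=7))


def toy_lesion_matrix(rng, n_subjects=20, n_voxels=500, p=0.3, shape=(10, 10, 5)):
    """A random binary design wrapped as a LesionMatrix (no filtering)."""
    assert n_voxels <= np.prod(shape)
    X = (rng.random((n_subjects, n_voxels)) < p).astype(np.uint8)
    X[:, X.sum(0) == 0] = 1  # no empty columns
    return LesionMatrix(
        matrix=X,
        voxel_index=np.arange(n_voxels),
        grid_shape=shape,
        affine=np.eye(4),
        voxel_dims=(1.0, 1.0, 1.0),
        subject_ids=tuple(f"s{i}" for i in range(n_subjects)),
        lesion_volumes_mm3=X.sum(1).astype(float),
        filter_min_subjects=1,
    )


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(123)
    lm = toy_lesion_matrix(rng)
    return lm, compress_patches(lm)
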