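import numpy as np
import pytest

from mrsifp.basis import default_basis
from mrsifp.synthetic import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def basis():
    return default_basis(0.5, 4.2, 512)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (2 AC / 2 OG / 1 GBM, small voxel counts) for unit tests."""
    cfg = SyntheticCohortConfig(
        n_patients_per_subtype={"AC": 2, "OG": 2, "GBM": 1},
        tumor_voxels_per_patient=(8, 20),
        healthy_voxels_per_patient=(23, 60),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
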