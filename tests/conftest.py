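import numpy as np
import pytest

from rsiscope.cohort import AcquisitionProtocol, CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


def small_cohort_config(**overrides) -> CohortConfig:
    """A cohort small enough for unit tests but geometrically valid."""
    defaults = dict(
        n_patients=10,
        grid_shape=(14, 14, 8),
        voxel_size_mm=(2.5, 2.5, 6.0),
        prostate_radii_mm=(12.0, 10.0, 10.0),
        central_radii_mm=(6.0, 5.0, 6.5),
        lesion_radii_mm=(5.0, 5.0, 6.5),
        seed=3,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
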