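import numpy as np
import pytest

from srct_radiomics import CohortConfig, generate_cohort

# Small phantom geometry used throughout the suite: short z so the
# nine-slice protocol still fits, coarse in-plane grid for speed.
SMALL_SHAPE = (48, 40, 40)
SMALL_SPACING = (3.0, 2.5, 2.5)


def small_config(**overrides) -> CohortConfig:
    base = dict(
        n_none=6, n_limited=5, n_extensive=5,
        volume_shape=SMALL_SHAPE, voxel_spacing=SMALL_SPACING,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient cohort shared by read-only tests."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def one_diseased_patient(small_cohort):
    return next(p for p in small_cohort if p.label == "extensive")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240830)
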