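import logging

import numpy as np
import pytest

from disconnectomics import PhantomSpec, generate_cohort
from disconnectomics.volumes import ImageVolume

logging.getLogger("disconnectomics").setLevel(logging.ERROR)


@pytest.fixture
def grid16() -> ImageVolume:
    """16^3 grid at 2 mm isotropic, origin at world (0, 0, 0)."""
    return ImageVolume(np.zeros((16, 16, 16), dtype=np.float32),
                       np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-subject, 5-control synthetic cohort reused across test modules."""
    return generate_cohort(
        spec=PhantomSpec(n_controls=5), n_subjects=24, seed=7
    )
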