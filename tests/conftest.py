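import numpy as np
import pytest

from retquant.geometry import build_field_layout
from retquant.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def od_layout():
    """A canonical right-eye layout: disc nasal-superior of the fovea."""
    return build_field_layout((-15.5, 1.5), (0.0, 0.0), "OD")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten eyes per ICDR level with designed-truth labels (seeded)."""
    config = CohortConfig(eyes_per_level=(10, 10, 10, 10, 10), seed=99)
    eyes, truths = generate_cohort(config)
    return config, eyes, truths
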