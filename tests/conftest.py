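import numpy as np
import pytest

from idsim.simulate import generate_cohort, miniature_config

from _cohorts import small_cohort_config


@pytest.fixture(scope="session")
def miniature_cohort():
    """The packaged miniature dataset: 8 subjects, 4 ROIs, 8 videos."""
    return generate_cohort(miniature_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """28 subjects, 3 toy ROIs on the compact grid, no planted effects."""
    return generate_cohort(small_cohort_config(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
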