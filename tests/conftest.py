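import numpy as np
import pytest

from varsense.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (88-variant truth set, 17-normal PON)."""
    return generate_cohort(CohortConfig(seed=100))


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))
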