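import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ntcpvalid import CohortRecipe, generate_cohort, load_nipp_model

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def nipp():
    """The packaged NIPP grade II-IV dysphagia model."""
    return load_nipp_model()


@pytest.fixture(scope="session")
def default_cohort():
    """A 277-patient cohort generated from the default recipe."""
    return generate_cohort(CohortRecipe(n=277, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A larger cohort for consistency checks."""
    return generate_cohort(CohortRecipe(n=5000, seed=23))


@pytest.fixture
def rng():
    return np.random.default_rng(2209)
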