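import numpy as np
import pytest
from hypothesis import settings

from nephrotext.backends import make_mock_backend
from nephrotext.cohort import generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """60 synthetic patients, default severity mix."""
    return generate_cohort(60, seed=3)


@pytest.fixture(scope="session")
def full_cohort():
    """195 synthetic patients at the 39/156 mild/severe mix."""
    return generate_cohort(195, seed=7)


@pytest.fixture(scope="session")
def mock_backends():
    """Primary + secondary mock backends at desk-scale geometry (D=32, L=8)."""
    primary = make_mock_backend("mock-primary", 32, 8, seed=0, role="primary")
    secondary = make_mock_backend("mock-secondary", 32, 8, seed=1, role="secondary")
    return primary, secondary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
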