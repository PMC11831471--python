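import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bpmsim import RateConstants

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rates():
    """Package-default rate constants (k_off shared by both interactions)."""
    return RateConstants()


@pytest.fixture(scope="session")
def slow_rates():
    """Rates with distinct dissociation constants for closed-form checks."""
    return RateConstants(k_on=1e5, k_off_analyte=0.03, k_on_star=0.01, k_off_bond=0.03)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
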