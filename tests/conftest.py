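import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flimcyte.decay import InstrumentResponse

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def irf():
    """The generator's default instrument response."""
    return InstrumentResponse(center=488.0, fwhm=250.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
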