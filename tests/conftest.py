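import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: One fixed seed for every stochastic check in the suite.
SUITE_SEED = 761204


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)
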