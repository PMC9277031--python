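import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedoct.phantom import PhantomConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def config():
    """Default-geometry phantom with a fixed seed."""
    return PhantomConfig(seed_rng=11)


@pytest.fixture
def fast_config():
    """Reduced-lateral-width phantom for Monte-Carlo style tests."""
    return PhantomConfig(seed_rng=11, n_lateral=300)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
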