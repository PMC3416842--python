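import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_patterns():
    """Tiny pattern set shared by oracle comparisons (N=6, P=3)."""
    from mixnet import generate_random_patterns

    return generate_random_patterns(6, 3, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
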