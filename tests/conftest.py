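import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Four well-separated blobs at the unit-square corners with their
    generating codes."""
    from embc.fixtures import four_blobs

    return four_blobs(n_per=100, seed=7)


@pytest.fixture
def synth400():
    """Default synthetic dataset: n=400, gamma=0.05, Markov states."""
    import embc

    return embc.simulate(embc.SyntheticConfig(n=400, gamma=0.05, seed=7))
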