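import numpy as np
import pytest

from reservoir_events.dynamics import IntegratorParams, init_reservoir
from reservoir_events.synthetic import gaussian_abcd_pair, gen_topic_stream


@pytest.fixture(scope="session")
def small_reservoir():
    """A modest reservoir for tests that only need qualitative dynamics."""
    return init_reservoir(N=120, K=20, alpha=0.05, seed=7)


@pytest.fixture(scope="session")
def integrator():
    return IntegratorParams(alpha=0.05, D=20)


@pytest.fixture(scope="session")
def topic_stream():
    return gen_topic_stream(8, 25, 100, topic_sep=10.0, noise_sd=1.0, seed=3)


@pytest.fixture(scope="session")
def abcd_pair():
    return gaussian_abcd_pair(30, 60, 30, 20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
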