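import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from taskspace import (
    ReservoirParams,
    build_reservoir_weights,
    make_reversal_schedule,
    ReversalConfig,
)


@pytest.fixture(scope="session")
def small_params():
    return ReservoirParams(N=40, g=2.0, tau=100.0, g_IR=4.0)


@pytest.fixture(scope="session")
def small_weights(small_params):
    return build_reservoir_weights(small_params, 3, seed=11)


@pytest.fixture()
def reversal_schedule():
    return make_reversal_schedule(0, 1, ReversalConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
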