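import numpy as np
import pytest

from diffgillespie.promoters import TWO_STATE_X0, TwoStateParams, build_two_state


@pytest.fixture(scope="session")
def two_state_net():
    return build_two_state()


@pytest.fixture(scope="session")
def fig_params():
    """The benchmark parameter point: kon=0.5, koff=1, r=10, gamma=1."""
    return TwoStateParams(kon_r=0.5, koff_r=1.0, r=10.0, gamma=1.0)


@pytest.fixture(scope="session")
def x0():
    return TWO_STATE_X0.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
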