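import numpy as np
import pytest

from wmh_penumbra import relaxometry as rx
from wmh_penumbra.sequences import SCANNER_A_32ECHO, SCANNER_B_48ECHO, make_hardi_scheme


@pytest.fixture(scope="session")
def seq32():
    return SCANNER_A_32ECHO


@pytest.fixture(scope="session")
def seq48():
    return SCANNER_B_48ECHO


@pytest.fixture(scope="session")
def t2grid():
    return rx.T2Grid.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hardi():
    return make_hardi_scheme(60, 700.0, n_b0=1)


def two_pool_signal(mwf, ie_t2, flip, seq, s0=800.0):
    """Noiseless two-pool decay, shared across tests."""
    return s0 * (
        mwf * rx.epg_decay(20.0, seq, flip) + (1 - mwf) * rx.epg_decay(ie_t2, seq, flip)
    )


@pytest.fixture(scope="session")
def two_pool():
    return two_pool_signal
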