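import numpy as np
import pytest

from microdose import KASE_HSG, make_log_grid


@pytest.fixture(scope="session")
def tepc_grid():
    """Standard 150-bin, 7-decade lineal-energy grid starting at 0.01 keV/um."""
    return make_log_grid(0.01, 7, 150)


@pytest.fixture
def kase():
    return KASE_HSG


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
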