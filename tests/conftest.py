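import numpy as np
import pytest

from lfpvc import SourceParams, simulate_session

SMALL_COUNTS = {"Wake": 6, "NREM": 14, "REM": 12}


@pytest.fixture(scope="session")
def small_session():
    """A 480 s default-parameter session shared by the analysis tests."""
    return simulate_session(SMALL_COUNTS, SourceParams(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
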