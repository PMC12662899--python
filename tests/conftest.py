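import numpy as np
import pytest

from swallowseg.embedding import MelStatsBackend


@pytest.fixture(scope="session")
def backend():
    return MelStatsBackend()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
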