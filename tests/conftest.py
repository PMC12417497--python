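import numpy as np
import pytest
from hypothesis import settings

from spindlearm.circuit import build_connectome

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def complete():
    return build_connectome("complete")


@pytest.fixture(scope="session")
def simple():
    return build_connectome("simple")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
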