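import numpy as np
import pytest

from shrubice import synthdata


@pytest.fixture(scope="session")
def tiny_study():
    """Small 4-site synthetic study shared across integration tests."""
    return synthdata.make_fixture("tiny_study")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
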