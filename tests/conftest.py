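import numpy as np
import pytest

from fsisfdi import default_lut


@pytest.fixture(scope="session")
def small_lut():
    """60x60 lookup table, cheap enough to share across tests."""
    return default_lut(60, 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
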