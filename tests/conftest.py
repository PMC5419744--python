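import numpy as np
import pytest

from polexchange import ExchangeParams, PhotoParams


@pytest.fixture
def noiseless_photo():
    """Detection without noise or bleaching: intensity = unit x fluorophores."""
    return PhotoParams(bleach_lifetime_s=1e12, bg_mean=0.0, bg_sd=0.0)


@pytest.fixture
def default_exchange():
    return ExchangeParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
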