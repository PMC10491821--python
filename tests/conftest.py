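import numpy as np
import pytest

from hatchsex.constants import PUBLISHED_FITS


@pytest.fixture(scope="session")
def naive_fits():
    return PUBLISHED_FITS["naive_female"], PUBLISHED_FITS["naive_male"]


@pytest.fixture(scope="session")
def challenged_fits():
    return PUBLISHED_FITS["challenged_female"], PUBLISHED_FITS["challenged_male"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
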