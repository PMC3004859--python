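import numpy as np
import pytest

from bcrnet.lyn_syk import OdeParameters


@pytest.fixture
def default_params() -> OdeParameters:
    return OdeParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
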