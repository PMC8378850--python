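import numpy as np
import pytest

from aeroring.params import MeanFieldParams, PottsParams


@pytest.fixture
def mf_params() -> MeanFieldParams:
    return MeanFieldParams()


@pytest.fixture
def potts_params() -> PottsParams:
    return PottsParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
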