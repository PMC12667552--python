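import numpy as np
import pytest

from eoskit.targets import STORAGE_FRAGMENT, TARGETS


@pytest.fixture
def fragment() -> str:
    return STORAGE_FRAGMENT


@pytest.fixture
def nine_mer() -> str:
    return TARGETS["nine_mer"].sequence


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
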