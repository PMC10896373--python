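import numpy as np
import pytest

from iclsim.category_tasks import FeatureSpace
from iclsim.encoding import build_vocab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def space():
    return FeatureSpace()


@pytest.fixture(scope="session")
def small_space():
    # small pool keeps vocabularies (and models) tiny in unit tests
    return FeatureSpace(pool_size=10, values_per_dim=8)


@pytest.fixture(scope="session")
def category_vocab(space):
    return build_vocab("category", space)


@pytest.fixture(scope="session")
def small_category_vocab(small_space):
    return build_vocab("category", small_space)


@pytest.fixture(scope="session")
def grid_vocab():
    return build_vocab("compositional")
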