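import numpy as np
import pytest

from dicomanno.vocab import load_hierarchy, load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def hier():
    return load_hierarchy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
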