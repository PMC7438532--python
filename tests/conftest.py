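import numpy as np
import pytest

from excilat.meanfield import square_weights
from excilat.walkstats import LatticeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def square():
    return LatticeSpec.square()


@pytest.fixture(scope="session")
def chain():
    return LatticeSpec.chain()


@pytest.fixture(scope="session")
def weights10():
    """Square-lattice walk weights up to k = 10 (shared; cached)."""
    return square_weights(10)
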