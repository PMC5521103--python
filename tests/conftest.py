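import numpy as np
import pytest

from vigsdesign import DesignConstraints


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def defaults():
    return DesignConstraints()


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def dna():
    """Factory: dna(rng, n) -> random sequence."""
    return random_dna
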