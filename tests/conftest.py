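import numpy as np
import pytest

from ampfeat.alphabet import AMINO_ACIDS, load_alphabet


@pytest.fixture(scope="session")
def no_reduction():
    return load_alphabet("no_reduction")


@pytest.fixture(scope="session")
def hydro():
    return load_alphabet("hydro")


@pytest.fixture(scope="session")
def conform():
    return load_alphabet("conform")


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


@pytest.fixture
def random_31mer(rng):
    return "".join(rng.choice(list(AMINO_ACIDS), size=31))
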