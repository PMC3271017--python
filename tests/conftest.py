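import numpy as np
import pytest

from dyadsel import build_blosum62_rate_matrix, parse_newick
from dyadsel.data import load_domain41


@pytest.fixture(scope="session")
def model():
    return build_blosum62_rate_matrix()


@pytest.fixture(scope="session")
def domain41():
    """Bundled 41-leaf, 70-residue synthetic domain fixture (tree, root)."""
    return load_domain41()


@pytest.fixture()
def cherry():
    return parse_newick("(A:0.1,B:0.2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
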