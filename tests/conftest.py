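import numpy as np
import pytest

from seedclust.alphabet import build_reduced_alphabet
from seedclust.extend_align import ExtendParams, build_score_matrix


@pytest.fixture(scope="session")
def alphabet():
    return build_reduced_alphabet()


@pytest.fixture(scope="session")
def score_matrix():
    return build_score_matrix()


@pytest.fixture(scope="session")
def extend_params():
    return ExtendParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n):
    from seedclust.alphabet import STANDARD_RESIDUES

    return "".join(rng.choice(list(STANDARD_RESIDUES), size=n))
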