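import numpy as np
import pytest

from ohnoscope.io_formats import Alignment
from ohnoscope.subst_model import build_rate_matrix, load_model
from ohnoscope.synthetic_data import make_fig6_bundle


@pytest.fixture(scope="session")
def lg_model():
    return load_model("LG")


@pytest.fixture(scope="session")
def binary_model():
    """Two-state symmetric model: Q = [[-1, 1], [1, -1]] after
    normalization, with the closed form P_same(t) = (1 + e^{-2t}) / 2."""
    s = np.array([[0.0, 1.0], [1.0, 0.0]])
    return build_rate_matrix(s, np.array([0.5, 0.5]), alphabet="AR")


@pytest.fixture(scope="session")
def fig6_bundle():
    """The shipped mutation/reversion scenario fixture (deterministic)."""
    return make_fig6_bundle(seed=7)


def random_reversible_model(rng, n_states, alphabet="ARNDCQEGHILKMFPSTWYV"):
    s = rng.random((n_states, n_states))
    s = s + s.T
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.ones(n_states) * 5.0)
    return build_rate_matrix(s, pi, alphabet=alphabet[:n_states])


def random_alignment(rng, names, n_cols, alphabet, gap_frac=0.0):
    seqs = []
    for _ in names:
        chars = [alphabet[rng.integers(0, len(alphabet))]
                 for _ in range(n_cols)]
        for i in range(n_cols):
            if rng.random() < gap_frac:
                chars[i] = "-"
        seqs.append("".join(chars))
    return Alignment(tuple(names), tuple(seqs))
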