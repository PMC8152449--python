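import numpy as np
import pytest
import scipy.sparse as sp

from polyatree import ReadCompat, simulate_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_transcript_ambiguous():
    """Rows [[1,0],[0.5,0.5]] repeated: the classic ambiguous toy instance."""
    mat = sp.csr_matrix(np.array([[1.0, 0.0], [0.5, 0.5]]))
    return ReadCompat(mat, np.array([30, 30]))


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_transcriptome(n_genes=10, depth=5000, ambiguity=0.5, seed=1)


def random_tree_instance(n, rng):
    """A random valid tree plus interior break fractions, for property tests."""
    from polyatree import baseline_tree

    tree = baseline_tree(n, "random", seed=int(rng.integers(2**31)))
    y = rng.uniform(0.05, 0.95, size=n - 1)
    return tree, y
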