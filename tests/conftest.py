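import numpy as np
import pytest

from phylonom import msa, phylogeny as ph


class SimpleAlignment:
    """Minimal alignment protocol object for phylogeny-level tests."""

    def __init__(self, ids, rows):
        self.ids = list(ids)
        self.rows = list(rows)


@pytest.fixture(scope="session")
def wag():
    return ph.RateModel.wag()


@pytest.fixture(scope="session")
def poisson():
    return ph.RateModel.poisson()


@pytest.fixture
def make_alignment():
    return SimpleAlignment


@pytest.fixture
def random_sequence():
    def _make(length, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list(ph.AMINO_ACIDS), size=length))

    return _make


def simulate_on_tree(tree, model, length, seed):
    """Site-independent sequence evolution on an arbitrary tree (test helper,
    independent of the package's own generator)."""
    rng = np.random.default_rng(seed)
    pi = model.frequencies
    states = {id(tree.root): rng.choice(20, size=length, p=pi)}
    seqs = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        p = model.transition_matrix(node.length)
        cum = p.cumsum(axis=1)
        parent = states[id(node.parent)]
        u = rng.random(length)
        st = (u[:, None] > cum[parent]).sum(axis=1).clip(0, 19)
        states[id(node)] = st
        if node.is_leaf:
            seqs[node.name] = "".join(ph.AMINO_ACIDS[k] for k in st)
    return seqs


@pytest.fixture
def tree_simulator():
    return simulate_on_tree
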