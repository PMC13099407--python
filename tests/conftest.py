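import numpy as np
import pytest

from gdvflex.fixtures import make_cloud_structure, make_helix_structure


@pytest.fixture(scope="session")
def helix60():
    """A small jittered helical structure (60 residues, 240 atoms)."""
    return make_helix_structure(60, seed=7)


@pytest.fixture(scope="session")
def cloud40():
    """A compact globular cloud (40 residues, 160 atoms)."""
    return make_cloud_structure(40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_contact_graph(n, p, seed):
    """Seeded Erdős–Rényi graph used across orbit-count tests."""
    from gdvflex.contact_graph import ContactGraph

    r = np.random.default_rng(seed)
    upper = np.triu(r.random((n, n)) < p, k=1)
    return ContactGraph(n, np.argwhere(upper))
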