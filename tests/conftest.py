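import numpy as np
import pytest

from comorbnet import GeneSet, Interactome
from comorbnet.synthetic import generate_interactome

#: base seed for all fixed-seed statistical tests
BASE_SEED = 19817


@pytest.fixture(scope="session")
def net2000():
    """Desk-scale synthetic interactome shared by the heavier statistical tests."""
    return generate_interactome(2000, 3, seed=BASE_SEED)


@pytest.fixture()
def path_graph():
    """Path 1 - 2 - 3."""
    return Interactome.from_edges([(1, 2), (2, 3)], name="path3")


@pytest.fixture()
def random_graph_factory():
    """Seeded Erdos-Renyi-ish random simple graphs for oracle comparisons."""

    def make(n_nodes, n_edges, seed):
        rng = np.random.default_rng(seed)
        g = Interactome(name=f"random_{seed}")
        for n in range(1, n_nodes + 1):
            g.graph.add_node(n)
        added = 0
        while added < n_edges:
            a, b = rng.integers(1, n_nodes + 1, size=2)
            if a != b and not g.graph.has_edge(int(a), int(b)):
                g.graph.add_edge(int(a), int(b))
                added += 1
        g._invalidate()
        return g

    return make


def geneset(*ids, name="gs"):
    return GeneSet(name=name, ids=frozenset(ids))
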