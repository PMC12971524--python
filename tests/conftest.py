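import networkx as nx
import pytest

from swrnet import SynthConfig, generate


def _conf_graph(edges):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, confidence=900)
    return g


@pytest.fixture
def path5():
    """Path graph A-B-C-D-E."""
    return _conf_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def complete5():
    g = nx.complete_graph(["A", "B", "C", "D", "E"])
    nx.set_edge_attributes(g, 900, "confidence")
    return g


@pytest.fixture
def star5():
    """Hub H with leaves L1..L4."""
    return _conf_graph([("H", f"L{i}") for i in range(1, 5)])


def random_confidence_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"g{i:03d}" for i in range(n)})
    nx.set_edge_attributes(g, 700, "confidence")
    return g


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-module benchmark shared across test modules."""
    return generate(SynthConfig(n_genes=800, p_bg=0.006, n_sets=9, set_size=15,
                                n_drivers=40, n_decoys=100, p_signal=0.15,
                                p_noise=0.01, seed=5))
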