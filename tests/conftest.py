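import networkx as nx
import pytest

import walkrecon as wr


@pytest.fixture(scope="session")
def degree_probe_graph():
    """Hub 0 with neighbors of degrees 1, 2 and 3 — probes degree-biased steps.

    Neighbor degrees seen from node 0: node 1 -> 1, node 2 -> 2, node 3 -> 3.
    """
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (0, 3), (2, 7), (3, 8), (3, 9)])
    return g


@pytest.fixture(scope="session")
def branch_graph():
    """Path 0-1 then branch 1-2, 1-3: first move forced, second probes history."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (1, 3)])
    return g


@pytest.fixture(scope="session")
def small_connected_er():
    g = wr.generate_er(40, 5, seed=11)
    lcc, _ = wr.relabel_to_range(wr.largest_component(g))
    return lcc


@pytest.fixture(scope="session")
def dense_lfr():
    """Small, dense modular network whose planted structure Leiden can resolve."""
    params = wr.LFRParams(n_communities=5, mu=0.05, n_nodes=250, avg_degree=10.0)
    return wr.generate_lfr(params, seed=21)
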