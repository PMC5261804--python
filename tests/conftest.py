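import networkx as nx
import numpy as np
import pytest

from ppiscore.pathway_network import ContextNetwork
from ppiscore.simulate import SimulationConfig, generate_all


def make_context(edges, essentiality, cell_line="CL"):
    """Small context network from an edge list and a p-value map."""
    g = nx.Graph()
    g.add_edges_from(edges)
    nx.set_node_attributes(g, essentiality, "essentiality")
    return ContextNetwork(cell_line=cell_line, graph=g, node_essentiality=dict(essentiality))


def random_context(n_nodes, n_edges, seed, connected=True):
    """Random connected context network with uniform random essentialities."""
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed + 1000 * attempt)
        if not connected or nx.is_connected(g):
            break
    else:
        g = nx.connected_watts_strogatz_graph(n_nodes, 4, 0.3, seed=seed)
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes()})
    p = {n: float(rng.random()) for n in g.nodes()}
    return make_context(list(g.edges()), p, cell_line=f"rand{seed}")


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic study used across tests (fixed seed)."""
    return SimulationConfig(
        seed=20240917,
        n_proteins=80,
        n_pathways=5,
        pathway_size_range=(10, 20),
        n_cell_lines=16,
        n_patients=200,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Fully generated synthetic inputs for the small configuration."""
    sp, shrna, contexts, drug, mutations, clinical = generate_all(small_cfg)
    return {
        "cfg": small_cfg,
        "sp": sp,
        "shrna": shrna,
        "contexts": {c.cell_line: c for c in contexts},
        "drug": drug,
        "mutations": mutations,
        "clinical": clinical,
    }
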