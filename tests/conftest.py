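import networkx as nx
import numpy as np
import pytest

from stallflow import VascularNetwork


def make_chain_network(conductant_edges, pressures, kinds=None):
    """Hand-built network from (u, v, length_um, diameter_um, kind) tuples."""
    g = nx.Graph()
    for u, v, length, diam, kind in conductant_edges:
        g.add_edge(u, v, length_um=length, diameter_um=diam, kind=kind, stall_factor=1.0)
    for n in g.nodes:
        g.nodes[n].setdefault("pos", (0.0, 0.0, 0.0))
        g.nodes[n]["kind"] = (kinds or {}).get(n, "internal")
    return VascularNetwork(g, pressures)


@pytest.fixture
def single_tube():
    """One capillary between a pressure-fixed inlet and outlet."""
    return make_chain_network(
        [("in", "out", 60.0, 4.0, "capillary")],
        {"in": 20.0, "out": 10.0},
        kinds={"in": "inlet", "out": "outlet"},
    )


@pytest.fixture
def series_parallel():
    """Feed arteriole -> two parallel 2-capillary branches -> drain venule."""
    edges = [
        ("in", "a", 100.0, 10.0, "arteriole"),
        ("a", "m1", 60.0, 4.0, "capillary"),
        ("m1", "b", 60.0, 4.0, "capillary"),
        ("a", "m2", 60.0, 4.0, "capillary"),
        ("m2", "b", 60.0, 4.0, "capillary"),
        ("b", "out", 100.0, 12.0, "venule"),
    ]
    return make_chain_network(
        edges, {"in": 30.0, "out": 10.0}, kinds={"in": "inlet", "out": "outlet"}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
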