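import numpy as np
import pytest

from progchain import (
    DistanceGraph,
    ProgressionNetwork,
    WorldParams,
    simulate_world,
)


def make_network(edges, provenance="cDPN"):
    """Network from {(u, v): weight}; single provenance tag."""
    net = ProgressionNetwork()
    for (u, v), w in edges.items():
        net.add_edge(u, v, w, {provenance})
    return net


def make_distance_graph(arcs):
    """DistanceGraph from {(u, v): distance}."""
    nodes = {n for arc in arcs for n in arc}
    return DistanceGraph(nodes=set(nodes), arcs=dict(arcs))


def random_distance_graph(rng, n_nodes=10, arc_prob=0.2):
    """Random digraph with uniform arc distances in [0, 1]."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    arcs = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < arc_prob:
                arcs[(u, v)] = float(rng.random())
    return DistanceGraph(nodes=set(nodes), arcs=arcs)


def random_network(rng, n_nodes=20, arc_prob=0.2):
    net = ProgressionNetwork()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    for n in nodes:
        net.add_node(n)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < arc_prob:
                net.add_edge(u, v, float(rng.random()), {"tDPN"})
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_world():
    """One synthetic world at default study conditions, shared per session."""
    return simulate_world(WorldParams(seed=0))


@pytest.fixture(scope="session")
def default_layers(default_world):
    from progchain import build_all_layers

    return build_all_layers(default_world)
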