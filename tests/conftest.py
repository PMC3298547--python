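import numpy as np
import pytest

from priornet.netcore import DirectedNetwork
from priornet.synthdata import SimConfig, simulate_all


def random_network(rng: np.random.Generator, n_max: int = 50,
                   labeled: bool = False) -> DirectedNetwork:
    """A small random digraph (used across property tests)."""
    n = int(rng.integers(2, n_max + 1))
    names = [f"n{i:02d}" for i in range(n)]
    net = DirectedNetwork(name="random")
    for v in names:
        net.add_vertex(v)
    m = int(rng.integers(0, max(1, 3 * n)))
    labels = ["act", "inh", None]
    for _ in range(m):
        a, b = rng.integers(n, size=2)
        if a == b:
            continue
        lab = labels[int(rng.integers(3))] if labeled else None
        net.add_edge(names[a], names[b], lab)
    return net


@pytest.fixture
def toy_net() -> DirectedNetwork:
    """Path a->b->c plus orphan z."""
    net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")], vertices=["z"])
    return net


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Down-scaled generator config for fast pipeline tests."""
    return SimConfig(
        seed=7,
        n_vertices=120,
        n_edges=300,
        core_size=20,
        in_size=30,
        out_size=35,
        n_pathways=12,
        mean_pathway_size=8,
        n_tissues=10,
        library_size_normal=5000,
        library_size_disease=5000,
        n_enzymes=25,
        n_substrates=400,
        currency_reactions=40,
        n_currency=2,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate_all(small_cfg)
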