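import networkx as nx
import pytest

from netmod.interactome import Interactome
from netmod.synthetic import SyntheticConfig, generate_interactome


@pytest.fixture
def toy_graph() -> Interactome:
    """8-node example: edges A-C, B-C, A-D, D-E, B-F, G-H."""
    g = nx.Graph([("A", "C"), ("B", "C"), ("A", "D"), ("D", "E"), ("B", "F"), ("G", "H")])
    return Interactome(g)


@pytest.fixture
def path_graph() -> Interactome:
    g = nx.path_graph(["A", "B", "C", "D"])
    return Interactome(g)


@pytest.fixture(scope="session")
def small_synthetic():
    """500-node scale-free graph with a 30-node planted module, 8 seeds."""
    cfg = SyntheticConfig(
        n_nodes=500, planted_size=30, planted_p=0.3, n_seeds=8, rng_seed=42
    )
    g, truth = generate_interactome(cfg)
    return cfg, g, truth


@pytest.fixture(scope="session")
def dual_synthetic():
    """Two planted modules sharing 5 proteins (connector fixture)."""
    cfg = SyntheticConfig(
        n_nodes=600, planted_size=30, planted_p=0.35, n_seeds=8,
        n_modules=2, overlap=5, rng_seed=7,
    )
    g, truth = generate_interactome(cfg)
    return cfg, g, truth
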