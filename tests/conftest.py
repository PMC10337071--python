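import networkx as nx
import numpy as np
import pytest

from phyllonet import GeneratorConfig, generate_community, generate_saponins


@pytest.fixture(scope="session")
def default_draw():
    """One generator draw at study-scale defaults (27 samples)."""
    cfg = GeneratorConfig(seed=1)
    abund, env, coords, truth = generate_community(cfg)
    return cfg, abund, env, coords, truth


@pytest.fixture(scope="session")
def recovery_draw():
    """Larger draw (n=200) used to stabilize stochastic recovery assertions."""
    cfg = GeneratorConfig(seed=11, n_samples=200)
    abund, env, coords, truth = generate_community(cfg)
    sap = generate_saponins(abund, truth, cfg, env=env)
    return cfg, abund, env, coords, truth, sap


@pytest.fixture(scope="session")
def lownoise_draw():
    """Low-noise draw (n=200) for structure-recovery invariants."""
    cfg = GeneratorConfig(seed=1, n_samples=200, noise_sd=0.15)
    abund, env, coords, truth = generate_community(cfg)
    return cfg, abund, env, coords, truth


@pytest.fixture
def small_graphs():
    """Named small graphs with hand-checkable metric values."""
    path3 = nx.path_graph(3)
    k3 = nx.complete_graph(3)
    star = nx.star_graph(5)
    two_edges = nx.Graph([(0, 1), (2, 3)])
    two_cliques = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    two_cliques.add_edge(2, 3)
    return {
        "path3": path3,
        "k3": k3,
        "star": star,
        "two_edges": two_edges,
        "two_cliques": two_cliques,
    }


@pytest.fixture
def random_graphs():
    """A bag of random graphs (<= 50 nodes) for oracle-equivalence checks."""
    graphs = []
    for seed in range(6):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        p = float(rng.uniform(0.05, 0.4))
        graphs.append(nx.gnp_random_graph(n, p, seed=seed))
    return graphs
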