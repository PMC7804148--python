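import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netmodmut as nm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A small seeded two-cohort simulation shared across tests."""
    cfg = nm.SimConfig(n_samples=150, n_genes=60, module_size=5, n_background_edges=120, seed=7)
    return nm.make_two_cohorts(cfg)


@pytest.fixture()
def triangle_graph():
    """Isolated unit-weight triangle."""
    g = nx.Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v, weight=1.0)
    return g


def random_weighted_graph(n, p, seed):
    """Random graph with uniform(0, 1] edge weights, gene-like string labels."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(n)})
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return g
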