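import networkx as nx
import numpy as np
import pandas as pd
import pytest

from riccirank import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic panel shared across integration tests."""
    cfg = SyntheticConfig(
        n_genes=60,
        n_cell_lines=24,
        n_tissues=4,
        n_modules=4,
        n_drugs=6,
        missing_rate=0.02,
        seed=3,
    )
    return make_dataset(cfg)


@pytest.fixture()
def weighted_triangle():
    G = nx.Graph()
    G.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return G


def random_connected_weighted_graph(rng, n_lo=5, n_hi=12, max_degree=None, integer_weights=False):
    """Random connected simple graph: a tree plus a few extra edges."""
    n = int(rng.integers(n_lo, n_hi + 1))
    G = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.choice(n, size=2, replace=False)
        if u != v and not G.has_edge(u, v):
            if max_degree and (G.degree(u) >= max_degree or G.degree(v) >= max_degree):
                continue
            G.add_edge(int(u), int(v))
    for u, v in G.edges:
        w = int(rng.integers(1, 4)) if integer_weights else float(rng.uniform(0.05, 1.0))
        G[u][v]["weight"] = w
    return G
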