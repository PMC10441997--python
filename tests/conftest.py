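import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_table():
    """3 taxa x 4 samples with known counts."""
    return pd.DataFrame(
        [[5, 0, 2, 1], [3, 7, 0, 4], [2, 3, 8, 5]],
        index=["tA", "tB", "tC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_signed_network(rng, n=10, p_edge=0.45, p_neg=0.3):
    """Random signed co-occurrence-style graph with abundance attributes."""
    g = nx.Graph()
    ab = rng.uniform(0.2, 1.0, size=n)
    ab = ab / ab.sum()
    for i in range(n):
        g.add_node(f"n{i:02d}", abundance=float(ab[i]))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w = rng.uniform(0.6, 0.95)
                if rng.random() < p_neg:
                    w = -w
                g.add_edge(f"n{i:02d}", f"n{j:02d}", weight=float(w), q=0.001)
    return g


@pytest.fixture
def signed_network_factory(rng):
    return lambda **kw: random_signed_network(rng, **kw)
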