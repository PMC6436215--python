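import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

logging.getLogger("drugmod").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expression():
    genes = [f"G{i}" for i in range(6)]
    cells = [f"C{i}" for i in range(5)]
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.uniform(5, 10, size=(6, 5)), index=genes,
                        columns=cells)


@pytest.fixture
def small_response():
    cells = [f"C{i}" for i in range(5)]
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(3, 5)),
                      index=["d1", "d2", "d3"], columns=cells)
    df.iloc[0, 0] = np.nan
    return df


@pytest.fixture
def ring_graph():
    return nx.cycle_graph(30)


def random_connected_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    p = max(p, 1.3 * np.log(n) / n)  # stay above the connectivity threshold
    for attempt in range(100):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes()})
    raise RuntimeError("could not draw a connected graph")
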