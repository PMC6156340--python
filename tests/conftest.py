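import networkx as nx
import numpy as np
import pandas as pd
import pytest

from divmap import CellTable, WeightsGraph


def make_cells(n=20, seed=0, cell_class="cancer", width=1000.0, height=1000.0):
    """Small well-formed cell table for unit tests."""
    rng = np.random.default_rng(seed)
    area = rng.lognormal(np.log(30.0), 0.3, n)
    s = 1.0 + np.exp(rng.normal(-1.5, 0.5, n))
    df = pd.DataFrame({
        "cell_id": np.arange(n),
        "x": rng.uniform(0, width, n),
        "y": rng.uniform(0, height, n),
        "cell_class": cell_class,
        "nucleus_area": area,
        "nucleus_perimeter": s * 2 * np.sqrt(np.pi * area),
    })
    return CellTable(df, slide_id=f"test-{seed}")


def weights_from_edges(n, edges):
    """WeightsGraph over nodes 0..n-1 with the given undirected edges."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return WeightsGraph(g)


def complete_weights(n):
    return WeightsGraph(nx.complete_graph(n))


@pytest.fixture
def small_table():
    return make_cells(n=60, seed=1)


@pytest.fixture
def mixed_table():
    """Table with all three cell classes."""
    rng = np.random.default_rng(3)
    parts = []
    for i, (cls, n) in enumerate([("cancer", 40), ("lymphocyte", 12),
                                  ("stromal", 8)]):
        t = make_cells(n=n, seed=10 + i, cell_class=cls).data
        t["cell_id"] = t["cell_id"] + 100 * i
        parts.append(t)
    df = pd.concat(parts, ignore_index=True)
    return CellTable(df, slide_id="mixed")
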