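import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle_utils importable

from mentalex import LexicalNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def graph_from_adj(adj: np.ndarray, weights: np.ndarray | None = None) -> LexicalNetwork:
    """LexicalNetwork from a 0/1 adjacency matrix (optional weight matrix)."""
    n = adj.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                w = float(weights[i, j]) if weights is not None else 1.0
                G.add_edge(i, j, weight=w)
    return LexicalNetwork(G)


@pytest.fixture
def triangle():
    G = nx.Graph()
    G.add_weighted_edges_from([("a", "b", 0.9), ("b", "c", 0.5), ("a", "c", 0.2)])
    return LexicalNetwork(G)
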