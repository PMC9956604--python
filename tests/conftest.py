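import numpy as np
import pytest

from ivambn.kgraph import KnowledgeGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_cliques_graph(k1: int = 4, k2: int = 4) -> KnowledgeGraph:
    """Two cliques joined by a single bridge edge (all causal relations)."""
    nodes = {f"A{i}": "gene" for i in range(k1)}
    nodes.update({f"B{i}": "gene" for i in range(k2)})
    edges = []
    for grp, k in (("A", k1), ("B", k2)):
        for i in range(k):
            for j in range(i + 1, k):
                edges.append((f"{grp}{i}", "increases", f"{grp}{j}"))
    edges.append(("A0", "increases", "B0"))
    return KnowledgeGraph(nodes=nodes, edges=edges)


@pytest.fixture
def bridged_cliques():
    return two_cliques_graph()
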