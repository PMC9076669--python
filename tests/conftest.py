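import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stressnet.datasets import CountMatrix, DiscreteDataset
from stressnet.synthetic import GroundTruthBN, sample_discrete, strong_cpts


@pytest.fixture(scope="session")
def chain_ab_bn() -> GroundTruthBN:
    """3 ternary variables; A strongly drives B, C independent."""
    dag = nx.DiGraph()
    dag.add_nodes_from(["A", "B", "C"])
    dag.add_edge("A", "B")
    return strong_cpts(dag, {"A": 3, "B": 3, "C": 3}, peak=0.9, seed=7)


@pytest.fixture(scope="session")
def chain_ab_data(chain_ab_bn) -> DiscreteDataset:
    return sample_discrete(chain_ab_bn, 1000, seed=11)


@pytest.fixture(scope="session")
def six_node_bn() -> GroundTruthBN:
    """Fixed 6-node, 6-edge ground truth with strong (low-concentration) CPTs."""
    dag = nx.DiGraph()
    dag.add_nodes_from([f"V{i}" for i in range(6)])
    dag.add_edges_from(
        [("V0", "V1"), ("V1", "V2"), ("V2", "V3"), ("V3", "V4"), ("V4", "V5"), ("V0", "V3")]
    )
    return strong_cpts(dag, {f"V{i}": 3 for i in range(6)}, peak=0.9, seed=13)


@pytest.fixture(scope="session")
def barbell() -> nx.Graph:
    """Two triangles joined by one bridge (7 edges)."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    )
    return g


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        np.array([[10, 90, 5, 7], [0, 0, 0, 0], [50, 40, 60, 55]]),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    cond = pd.Series([0, 0, 1, 1], index=counts.columns)
    return CountMatrix(counts, cond)
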