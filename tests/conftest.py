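import numpy as np
import pytest

from pavd.io import BinaryExpressionMatrix
from pavd.networks import PathwayNetwork, enumerate_candidates


def chain(pathway_id: str, genes: tuple[str, ...]) -> PathwayNetwork:
    edges = tuple((genes[i], genes[i + 1]) for i in range(len(genes) - 1))
    return PathwayNetwork(pathway_id, genes, edges)


def binary_matrix(rows: dict[str, list[int]], sample_ids=None) -> BinaryExpressionMatrix:
    genes = list(rows)
    values = np.array([rows[g] for g in genes])
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return BinaryExpressionMatrix(genes, sample_ids, values)


def random_dag(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.4) -> PathwayNetwork:
    """Random DAG via a random topological order with forward edges only."""
    names = [f"G{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((order[i], order[j]))
    return PathwayNetwork("random", tuple(names), tuple(edges))


@pytest.fixture
def two_gene_data() -> BinaryExpressionMatrix:
    return binary_matrix({"A": [1, 0], "B": [1, 0]})


@pytest.fixture
def ab_family():
    return enumerate_candidates(PathwayNetwork("p", ("A", "B"), (("A", "B"),)))
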