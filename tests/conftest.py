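import networkx as nx
import numpy as np
import pytest

from netmark.expression import CANCER, NONCANCER, ExpressionMatrix
from netmark.interactions import InteractionSet
from netmark.pool import RoughNetwork


def make_matrix(data: dict, labels=None, normalized=True) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {symbol: vector}; rows sorted by symbol."""
    names = sorted(data)
    vals = np.vstack([np.asarray(data[k], dtype=float) for k in names])
    n = vals.shape[1]
    return ExpressionMatrix(
        entity_ids=names,
        sample_ids=[f"s{i}" for i in range(n)],
        values=vals,
        labels=labels,
        normalized=normalized,
    )


def star_network(target: str, neighbors: list[str], cap: int = 10_000) -> RoughNetwork:
    g = nx.Graph()
    for q in neighbors:
        g.add_edge(target, q)
    return RoughNetwork(proteins=sorted(g.nodes), graph=g, degree_cap=cap)


def ppi_from_pairs(pairs) -> InteractionSet:
    ppi = InteractionSet()
    for a, b in pairs:
        ppi.add(a, b)
    return ppi


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small on-disk fixture bundle with differential mean shift."""
    from netmark.synthetic import generate_fixture

    out = tmp_path_factory.mktemp("fixture")
    truth, paths = generate_fixture(
        out, K=30, n_edges=60, shared_fraction=0.7,
        n_cancer=60, n_noncancer=60, mean_shift=0.5, seed=11,
    )
    return truth, paths
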