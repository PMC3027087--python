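"""Network-difference node scoring with a structure-permutation null.

The two phenotype association networks are compared elementwise; each
protein's relevance score is the row sum of absolute differences.  An
empirical p-value is attached by repeatedly reassigning the observed edge
difference magnitudes to uniformly random node pairs (edge count preserved,
degree sequence not), pooling the per-node scores of every random structure
into one null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .inference import AssociationNetwork
from .pool import RoughNetwork

logger = logging.getLogger(__name__)


@dataclass
class DifferenceMatrix:
    """Elementwise difference between the two association networks."""

    proteins: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.proteins = list(self.proteins)
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.proteins)
        if self.matrix.shape != (k, k):
            raise ContractError(f"matrix shape {self.matrix.shape} != ({k}, {k})")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ContractError("difference matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ContractError("difference matrix diagonal must be zero")


def difference_matrix(cpan: AssociationNetwork, npan: AssociationNetwork) -> DifferenceMatrix:
    """Cancer-network matrix minus non-cancer-network matrix."""
    if cpan.proteins != npan.proteins:
        diff = sorted(set(cpan.proteins) ^ set(npan.proteins))
        raise ContractError(f"protein lists differ between networks: {diff}")
    return DifferenceMatrix(proteins=list(cpan.proteins), matrix=cpan.matrix - npan.matrix)


def compute_crv(d: DifferenceMatrix) -> np.ndarray:
    """Per-protein relevance score: row sum of absolute differences.

    Accumulates column by column (plain left-to-right summation) so the
    result is bit-identical to a naive double-loop evaluation.
    """
    k = d.matrix.shape[0]
    out = np.zeros(k)
    a = np.abs(d.matrix)
    for j in range(k):
        out += a[:, j]
    return out


@dataclass
class CRVTable:
    """Relevance scores with empirical p-values, sorted by descending score.

    ``table`` columns: protein, crv, p_value (numeric; below-resolution
    results stored as half the resolution), p_label (display string, e.g.
    "< 1e-05"), significant.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int
    #: mean of all pooled null scores (diagnostic; equals 2|E|/K * mean|d_e|)
    null_mean: float = float("nan")

    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]].reset_index(drop=True)


def permutation_null(
    net: RoughNetwork,
    d: DifferenceMatrix,
    n_permutations: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CRVTable:
    """Empirical p-values for the observed relevance scores.

    Each replicate reassigns the observed multiset of edge difference
    magnitudes to distinct random node pairs (no self-pairs, edge count
    preserved) and records all per-node scores; the scores of every
    replicate are pooled into one null distribution.  A protein's p-value
    is the fraction of pooled null scores at least as large as its observed
    score.  Zero counts are reported as below the resolution of the run.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    if net.proteins != d.proteins:
        raise ContractError("rough network and difference matrix protein lists differ")
    k = len(d.proteins)
    idx = net.index()
    edges = net.edges()
    support = set(zip(*np.nonzero(np.triu(d.matrix, 1))))
    edge_idx = {(idx[a], idx[b]) for a, b in edges}
    if not support <= edge_idx:
        raise ContractError("difference-matrix support is not a subset of the rough network edges")

    vals = np.array([abs(d.matrix[idx[a], idx[b]]) for a, b in edges])
    m = len(edges)
    n_pairs = k * (k - 1) // 2
    iu, ju = np.triu_indices(k, 1)

    obs = compute_crv(d)
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]

    rng = np.random.default_rng(seed)
    # counts[r] accumulates null scores whose rank against sorted_obs is r
    counts = np.zeros(k + 1, dtype=np.int64)
    null_sum = 0.0
    for _ in range(n_permutations):
        sel = rng.choice(n_pairs, size=m, replace=False)
        null_crv = np.zeros(k)
        np.add.at(null_crv, iu[sel], vals)
        np.add.at(null_crv, ju[sel], vals)
        null_sum += float(null_crv.sum())
        ranks = np.searchsorted(sorted_obs, null_crv, side="right")
        counts += np.bincount(ranks, minlength=k + 1)

    # suffix sums: number of null scores >= sorted_obs[i]
    suffix = np.cumsum(counts[::-1])[::-1]
    count_ge_sorted = suffix[1:]
    count_ge = np.empty(k, dtype=np.int64)
    count_ge[order] = count_ge_sorted

    total = n_permutations * k
    p = count_ge / total
    below = count_ge == 0
    p_numeric = np.where(below, 0.5 / total, p)
    resolution_label = f"< {1.0 / n_permutations:g}"
    p_label = [resolution_label if b else f"{v:g}" for v, b in zip(p, below)]

    table = pd.DataFrame(
        {
            "protein": list(d.proteins),
            "crv": obs,
            "p_value": p_numeric,
            "p_label": p_label,
            "significant": p_numeric <= alpha,
        }
    ).sort_values(["crv", "protein"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return CRVTable(
        table=table,
        n_permutations=n_permutations,
        seed=seed,
        null_mean=null_sum / total,
    )


def refit_permutation_null(
    net: RoughNetwork,
    x,
    n_permutations: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    t_alpha: float = 0.05,
) -> CRVTable:
    """Fidelity-check null: full regression refits on permuted structures.

    Instead of redistributing observed edge difference magnitudes, each
    replicate draws a random structure with the same edge count, refits
    both phenotype association networks from the expression data, and
    pools the per-node scores of the resulting difference matrix.  Orders
    of magnitude slower than :func:`permutation_null`; intended for
    reduced replicate counts.
    """
    import networkx as nx

    from .expression import CANCER, NONCANCER
    from .inference import build_association_network

    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    k = net.n_proteins
    m = len(net.edges())
    cap = net.degree_cap
    n_pairs = k * (k - 1) // 2
    iu, ju = np.triu_indices(k, 1)

    def fit_diff(structure: RoughNetwork) -> DifferenceMatrix:
        cpan = build_association_network(structure, x, CANCER, t_alpha)
        npan = build_association_network(structure, x, NONCANCER, t_alpha)
        return difference_matrix(cpan, npan)

    d_obs = fit_diff(net)
    obs = compute_crv(d_obs)
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]

    rng = np.random.default_rng(seed)
    counts = np.zeros(k + 1, dtype=np.int64)
    null_sum = 0.0
    for _ in range(n_permutations):
        for _attempt in range(100):
            sel = rng.choice(n_pairs, size=m, replace=False)
            g = nx.Graph()
            g.add_nodes_from(net.proteins)
            for a, b in zip(iu[sel], ju[sel]):
                g.add_edge(net.proteins[a], net.proteins[b])
            if max(dict(g.degree).values()) < cap:
                break
        else:
            raise ContractError("could not sample a structure within the degree cap")
        structure = RoughNetwork._unchecked(net.proteins, g, cap)
        null_crv = compute_crv(fit_diff(structure))
        null_sum += float(null_crv.sum())
        counts += np.bincount(
            np.searchsorted(sorted_obs, null_crv, side="right"), minlength=k + 1
        )

    suffix = np.cumsum(counts[::-1])[::-1]
    count_ge = np.empty(k, dtype=np.int64)
    count_ge[order] = suffix[1:]
    total = n_permutations * k
    p = count_ge / total
    below = count_ge == 0
    p_numeric = np.where(below, 0.5 / total, p)
    label = f"< {1.0 / n_permutations:g}"
    table = pd.DataFrame(
        {
            "protein": list(d_obs.proteins),
            "crv": obs,
            "p_value": p_numeric,
            "p_label": [label if b else f"{v:g}" for v, b in zip(p, below)],
            "significant": p_numeric <= alpha,
        }
    ).sort_values(["crv", "protein"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return CRVTable(table=table, n_permutations=n_permutations, seed=seed,
                    null_mean=null_sum / total)


def significant_proteins(t: CRVTable, threshold: float = 0.05) -> CRVTable:
    """Rows with p <= threshold (inclusive boundary), order preserved."""
    sub = t.table.loc[t.table["p_value"] <= threshold].reset_index(drop=True)
    return CRVTable(table=sub, n_permutations=t.n_permutations, seed=t.seed)
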