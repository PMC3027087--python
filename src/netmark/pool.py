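"""Differential protein pool selection and rough PPI network construction.

Stage order: one-way ANOVA across the two phenotype groups with Bonferroni
correction, pool assembly (differential proteins with interaction records
plus highly connected interactors), then a degree-bounded interaction graph
over the pool.  The degree bound keeps every regression in the refinement
stage overdetermined: the maximum degree must stay below the smaller
phenotype group's sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, PipelineError
from .expression import CANCER, NONCANCER, ExpressionMatrix
from .interactions import InteractionSet

logger = logging.getLogger(__name__)


@dataclass
class DifferentialTable:
    """Per-protein ANOVA results with Bonferroni adjustment.

    ``table`` columns: protein, f_statistic, p_raw, p_bonferroni, selected,
    underflow.  ``selected`` requires both the adjusted p-value cut and, when
    an interaction set was supplied, at least one interaction record.
    """

    table: pd.DataFrame
    alpha: float
    n_tested: int

    def de_proteins(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "protein"])


def differential_test(
    x: ExpressionMatrix, alpha: float = 0.05, ppi: InteractionSet | None = None
) -> DifferentialTable:
    """One-way ANOVA per protein across the two phenotype groups.

    Two-group ANOVA: with two groups the F statistic equals the square of
    the pooled two-sample t statistic.  p-values that underflow to zero in
    degenerate separations are reported as the smallest positive double and
    flagged.
    """
    if not x.normalized:
        raise ContractError("differential_test requires a normalized matrix")
    if x.labels is None:
        raise ContractError("differential_test requires phenotype labels")
    sizes = x.group_sizes()
    if min(sizes.values()) < 2:
        raise ContractError(f"each phenotype group needs >= 2 samples, got {sizes}")

    a = x.values[:, x.group_indices(CANCER)]
    b = x.values[:, x.group_indices(NONCANCER)]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(a, b, axis=1)
    f = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    # Degenerate rows: zero within-group variance with distinct means gives
    # F = inf, p = 0; identical constant groups give nan.
    underflow = (p == 0.0) | np.isinf(f)
    p = np.where(underflow, np.nextafter(0.0, 1.0), p)
    nan = ~np.isfinite(p)
    if nan.any():
        p = np.where(nan, 1.0, p)
        f = np.where(nan, 0.0, f)

    n_tested = x.n_entities
    p_bonf = np.minimum(1.0, p * n_tested)
    selected = p_bonf < alpha
    if ppi is not None:
        has_ppi = np.array([ppi.degree(e) >= 1 for e in x.entity_ids])
        n_excl = int((selected & ~has_ppi).sum())
        if n_excl:
            logger.info(
                "differential_test: %d differential protein(s) excluded for lacking interaction records",
                n_excl,
            )
        selected = selected & has_ppi

    table = pd.DataFrame(
        {
            "protein": list(x.entity_ids),
            "f_statistic": f,
            "p_raw": p,
            "p_bonferroni": p_bonf,
            "selected": selected,
            "underflow": underflow,
        }
    )
    return DifferentialTable(table=table, alpha=alpha, n_tested=n_tested)


def select_pool(
    dt: DifferentialTable,
    ppi: InteractionSet,
    alpha: float | None = None,
    neighbor_threshold: int = 3,
) -> list[str]:
    """Assemble the protein pool.

    Pool = differentially expressed proteins having at least one interaction
    record, plus non-differential tested proteins interacting with at least
    ``neighbor_threshold`` of those.  Differential proteins without any
    interaction record are excluded.  Returns a sorted symbol list.
    """
    if alpha is None:
        alpha = dt.alpha
    tab = dt.table
    de_mask = tab["p_bonferroni"].to_numpy() < alpha
    nbrs = ppi.neighbors_map()

    de_with_ppi = [
        p for p, de in zip(tab["protein"], de_mask) if de and len(nbrs.get(p, ())) >= 1
    ]
    n_excluded = int(de_mask.sum()) - len(de_with_ppi)
    if n_excluded:
        logger.info("select_pool: excluded %d differential protein(s) without interactions", n_excluded)

    de_set = set(de_with_ppi)
    augmented = []
    for p, de in zip(tab["protein"], de_mask):
        if de or p in de_set:
            continue
        links = len(nbrs.get(p, set()) & de_set)
        if links >= neighbor_threshold:
            augmented.append(p)

    pool = sorted(de_set | set(augmented))
    logger.info(
        "select_pool: %d differential + %d connected protein(s) -> pool of %d",
        len(de_with_ppi), len(augmented), len(pool),
    )
    if not pool:
        raise PipelineError(
            "empty protein pool; relax the differential alpha or the neighbor threshold"
        )
    return pool


@dataclass
class RoughNetwork:
    """Undirected, unweighted interaction graph over the pool.

    Invariants: no self-edges, every protein has degree >= 1, and the
    maximum degree is strictly below ``degree_cap`` (the smaller phenotype
    group's sample size).
    """

    proteins: list[str]
    graph: nx.Graph
    degree_cap: int

    def __post_init__(self):
        self.proteins = list(self.proteins)
        if set(self.proteins) != set(self.graph.nodes):
            raise ContractError("protein list does not match graph nodes")
        degs = dict(self.graph.degree)
        if degs and max(degs.values()) >= self.degree_cap:
            raise ContractError(
                f"max degree {max(degs.values())} violates cap {self.degree_cap}"
            )
        if any(d < 1 for d in degs.values()):
            raise ContractError("isolated protein in rough network")

    @classmethod
    def _unchecked(cls, proteins, graph, degree_cap) -> "RoughNetwork":
        """Internal constructor that skips invariant validation.

        Used for randomized null structures, which may legitimately
        contain isolated nodes.
        """
        obj = object.__new__(cls)
        obj.proteins = list(proteins)
        obj.graph = graph
        obj.degree_cap = degree_cap
        return obj

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def neighbors(self, protein: str) -> list[str]:
        return sorted(self.graph.neighbors(protein))

    def degree(self, protein: str) -> int:
        return self.graph.degree(protein)

    def max_degree(self) -> int:
        return max(dict(self.graph.degree).values())

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


def build_rough_network(
    pool: list[str], ppi: InteractionSet, x: ExpressionMatrix
) -> RoughNetwork:
    """Link pool proteins sharing interactions; enforce the degree cap.

    The cap is ``min(n_cancer, n_noncancer)``.  Any protein at or above the
    cap has incident edges pruned, weakest absolute Pearson correlation
    (between endpoint expression rows) first, until its degree is
    ``cap - 1``; ties are broken lexicographically by partner symbol.
    Isolated proteins are removed.
    """
    if not pool:
        raise PipelineError("empty pool")
    if x.labels is None:
        raise ContractError("expression matrix must be labeled")
    sizes = x.group_sizes()
    cap = min(sizes[CANCER], sizes[NONCANCER])
    if cap < 2:
        raise ContractError(f"degree cap {cap} too small; group sizes {sizes}")

    pool_set = {p.upper() for p in pool}
    g = nx.Graph()
    g.add_nodes_from(sorted(pool_set))
    for a, b in ppi.sorted_pairs():
        if a in pool_set and b in pool_set:
            g.add_edge(a, b)

    row = x.row_index()

    def abs_corr(a: str, b: str) -> float:
        ia, ib = row.get(a), row.get(b)
        if ia is None or ib is None:
            return 0.0
        va, vb = x.values[ia], x.values[ib]
        sa, sb = va.std(), vb.std()
        if sa == 0.0 or sb == 0.0:
            return 0.0
        return abs(float(np.corrcoef(va, vb)[0, 1]))

    n_pruned = 0
    while True:
        violators = sorted(p for p in g.nodes if g.degree(p) >= cap)
        if not violators:
            break
        p = violators[0]
        weakest = min(g.neighbors(p), key=lambda q: (abs_corr(p, q), q))
        g.remove_edge(p, weakest)
        n_pruned += 1
        logger.debug("build_rough_network: pruned edge (%s, %s) to respect degree cap", p, weakest)
    if n_pruned:
        logger.info("build_rough_network: pruned %d edge(s) to keep max degree < %d", n_pruned, cap)

    isolated = sorted(p for p in g.nodes if g.degree(p) == 0)
    if isolated:
        g.remove_nodes_from(isolated)
        logger.info(
            "build_rough_network: removed %d isolated protein(s): %s",
            len(isolated), ", ".join(isolated[:10]) + ("..." if len(isolated) > 10 else ""),
        )
    if g.number_of_nodes() == 0:
        raise PipelineError("all pool proteins are isolated; no rough network can be built")

    return RoughNetwork(proteins=sorted(g.nodes), graph=g, degree_cap=cap)
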