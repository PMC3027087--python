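"""Per-protein linear association model fitting and network assembly.

Each pool protein's z-scored expression is modelled, within one phenotype
group, as a linear combination of its rough-network neighbors' expression
plus Gaussian noise (no intercept; rows are z-scored).  Gaussian maximum
likelihood therefore coincides with ordinary least squares.  Model order is
selected by backward stepwise elimination gated on AIC
(``n*ln(RSS/n) + 2k``), followed by a single two-sided t-test prune.  The
retained coefficients ("association abilities") for every target are
assembled into one symmetric matrix per phenotype; directional
disagreements are resolved by keeping whichever coefficient has the larger
absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ContractError
from .expression import ExpressionMatrix
from .pool import RoughNetwork

logger = logging.getLogger(__name__)

#: Floor applied to RSS inside the AIC to keep perfect fits finite.
RSS_FLOOR = 1e-12


def _aic(rss: float, n: int, k: int) -> float:
    return n * float(np.log(max(rss, RSS_FLOOR) / n)) + 2 * k


def _ols(y: np.ndarray, X: np.ndarray):
    """No-intercept OLS.  Returns (beta, rss, se, t, rank)."""
    n, k = X.shape
    if k == 0:
        rss = float(y @ y)
        e = np.empty(0)
        return e, rss, e.copy(), e.copy(), 0
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - k
    if dof <= 0:
        raise ContractError(f"model with {k} coefficients and {n} samples is underdetermined")
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    var = sigma2 * np.diag(xtx_inv)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    return beta, rss, se, t, rank


@dataclass
class TargetFit:
    """One target protein's association model within one phenotype."""

    target: str
    phenotype: str
    neighbors: list[str]
    alpha_hat: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    residual_variance: float
    aic: float
    n_samples: int
    rss: float = 0.0
    rank_deficient: bool = False
    perfect_fit: bool = False
    dropped: list[tuple[str, str]] = field(default_factory=list)
    _y: np.ndarray | None = field(default=None, repr=False, compare=False)
    _neighbor_rows: dict | None = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        return len(self.neighbors)

    def coefficient(self, neighbor: str) -> float:
        return float(self.alpha_hat[self.neighbors.index(neighbor)])

    def coefficient_pvalues(self) -> np.ndarray:
        dof = self.n_samples - self.k
        return 2.0 * stats.t.sf(np.abs(self.t_stat), dof)


def _fit(target, phenotype, neighbors, y, neighbor_rows, n, dropped) -> TargetFit:
    X = (
        np.column_stack([neighbor_rows[q] for q in neighbors])
        if neighbors
        else np.empty((n, 0))
    )
    beta, rss, se, t, rank = _ols(y, X)
    if neighbors and rank < len(neighbors):
        logger.warning(
            "fit_target_model: rank-deficient design for target %s (%s); smallest-norm solution used",
            target, phenotype,
        )
    fit = TargetFit(
        target=target,
        phenotype=phenotype,
        neighbors=list(neighbors),
        alpha_hat=beta,
        se=se,
        t_stat=t,
        residual_variance=rss / n,
        aic=_aic(rss, n, len(neighbors)),
        n_samples=n,
        rss=rss,
        rank_deficient=bool(neighbors) and rank < len(neighbors),
        perfect_fit=rss <= RSS_FLOOR,
        dropped=list(dropped),
        _y=y,
        _neighbor_rows=neighbor_rows,
    )
    return fit


def fit_target_model(
    target: str, net: RoughNetwork, x: ExpressionMatrix, phenotype: str
) -> TargetFit:
    """Fit the full association model of ``target`` on one phenotype group.

    Coefficients are the Gaussian MLE (= no-intercept OLS on z-scored
    rows); standard errors and t statistics use the standard linear-model
    covariance with ``n - k`` degrees of freedom.
    """
    if not x.normalized:
        raise ContractError("fit_target_model requires a normalized matrix")
    cols = x.group_indices(phenotype)
    neighbors = net.neighbors(target)
    n = len(cols)
    if len(neighbors) >= n:
        raise ContractError(
            f"target {target}: degree {len(neighbors)} >= group size {n}"
        )
    row = x.row_index()
    if target not in row:
        raise ContractError(f"target {target} absent from expression matrix")
    missing = [q for q in neighbors if q not in row]
    if missing:
        raise ContractError(f"neighbors absent from expression matrix: {missing}")
    y = x.values[row[target]][cols]
    neighbor_rows = {q: x.values[row[q]][cols] for q in neighbors}
    return _fit(target, phenotype, neighbors, y, neighbor_rows, n, [])


def refine_model(fit: TargetFit, t_alpha: float = 0.05) -> TargetFit:
    """Backward stepwise elimination gated on AIC, then a t-test prune.

    Repeatedly drops the neighbor with the smallest absolute t statistic
    and refits while the AIC decreases; afterwards any coefficient whose
    two-sided p-value is >= ``t_alpha`` is dropped and the model refit
    once.  The empty model is a valid outcome.
    """
    if fit._y is None or fit._neighbor_rows is None:
        raise ContractError("refine_model needs a fit produced by fit_target_model")
    cur = fit
    args = (fit.target, fit.phenotype)
    y, rows, n = fit._y, fit._neighbor_rows, fit.n_samples

    while cur.neighbors:
        # smallest |t| first; ties broken by neighbor symbol
        drop_i = min(
            range(cur.k), key=lambda i: (abs(float(cur.t_stat[i])), cur.neighbors[i])
        )
        drop_sym = cur.neighbors[drop_i]
        cand_neighbors = [q for q in cur.neighbors if q != drop_sym]
        cand = _fit(
            *args, cand_neighbors, y, rows, n,
            cur.dropped + [(drop_sym, "aic")],
        )
        if cand.aic < cur.aic:
            cur = cand
        else:
            break

    if cur.neighbors:
        pvals = cur.coefficient_pvalues()
        keep = [q for q, p in zip(cur.neighbors, pvals) if p < t_alpha]
        if len(keep) < cur.k:
            pruned = [(q, "ttest") for q in cur.neighbors if q not in keep]
            cur = _fit(*args, keep, y, rows, n, cur.dropped + pruned)
    return cur


def symmetrize_pairs(a_ij: float, a_ji: float) -> float:
    """Resolve two directional estimates into one association ability.

    Returns whichever value has the larger absolute value.  On an exact tie
    of absolute values the first argument wins; callers pass the estimate
    from the lexicographically smaller (target, neighbor) ordered fit first.
    """
    return a_ij if abs(a_ij) >= abs(a_ji) else a_ji


@dataclass
class AssociationNetwork:
    """Symmetric K×K association-ability matrix for one phenotype."""

    proteins: list[str]
    matrix: np.ndarray
    phenotype: str
    fits: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.proteins = list(self.proteins)
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.proteins)
        if self.matrix.shape != (k, k):
            raise ContractError(f"matrix shape {self.matrix.shape} != ({k}, {k})")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ContractError("association matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ContractError("association matrix diagonal must be zero")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def n_associations(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, 1)))

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.matrix, 1))):
            out.append((self.proteins[i], self.proteins[j], float(self.matrix[i, j])))
        return sorted(out)


def build_association_network(
    net: RoughNetwork,
    x: ExpressionMatrix,
    phenotype: str,
    t_alpha: float = 0.05,
) -> AssociationNetwork:
    """Fit + refine every target and assemble the symmetric network.

    Entry (i, k) holds target i's retained coefficient for neighbor k; the
    matrix is then symmetrized pairwise (larger absolute value wins) with a
    zero diagonal.  Per-target fits are kept on the result for auditing.
    """
    k = net.n_proteins
    idx = net.index()
    directed = np.zeros((k, k))
    fits: dict[str, TargetFit] = {}
    for target in net.proteins:
        fit = refine_model(fit_target_model(target, net, x, phenotype), t_alpha)
        fits[target] = fit
        i = idx[target]
        for q, a in zip(fit.neighbors, fit.alpha_hat):
            directed[i, idx[q]] = a

    sym = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            # proteins are sorted, so (i, j) is the lexicographically
            # smaller ordered (target, neighbor) fit
            v = symmetrize_pairs(float(directed[i, j]), float(directed[j, i]))
            sym[i, j] = sym[j, i] = v
    return AssociationNetwork(proteins=list(net.proteins), matrix=sym, phenotype=phenotype, fits=fits)


def exhaustive_best_aic(fit: TargetFit) -> float:
    """Minimum AIC over all neighbor subsets (testing aid; <= 10 neighbors)."""
    if fit._y is None or fit._neighbor_rows is None:
        raise ContractError("needs a fit produced by fit_target_model")
    if fit.k > 10:
        raise ContractError("exhaustive search limited to 10 neighbors")
    best = np.inf
    y, rows, n = fit._y, fit._neighbor_rows, fit.n_samples
    for r in range(fit.k + 1):
        for subset in combinations(fit.neighbors, r):
            cand = _fit(fit.target, fit.phenotype, list(subset), y, rows, n, [])
            best = min(best, cand.aic)
    return best
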