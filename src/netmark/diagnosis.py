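"""Mapping-error classification and diagnostic evaluation.

A query sample's z-scored expression vector ``z`` over the network's
proteins is compared against each association network ``A`` via the
residual norm ``||z - A z||``; the sample is assigned to whichever
phenotype's network self-explains it better (smaller mapping error, ties
resolved to non-cancer).  Helpers cover confusion metrics, a
random-network accuracy baseline, stratified cross-validation of the whole
pipeline, and within-cohort expression similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, PipelineError
from .expression import CANCER, NONCANCER, ExpressionMatrix, znormalize
from .inference import AssociationNetwork, build_association_network
from .interactions import InteractionSet
from .pool import build_rough_network

logger = logging.getLogger(__name__)


@dataclass
class DiagnosisRecord:
    sample_id: str
    z: np.ndarray
    me_c: float
    me_n: float
    predicted: str
    truth: str | None = None


@dataclass
class PerformanceSummary:
    n: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def mapping_errors(
    z: np.ndarray, cpan: AssociationNetwork, npan: AssociationNetwork
) -> tuple[float, float]:
    """Euclidean norms of ``z - C z`` and ``z - N z``."""
    z = np.asarray(z, dtype=float)
    if z.shape != (cpan.n_proteins,) or cpan.n_proteins != npan.n_proteins:
        raise ContractError(
            f"query vector length {z.shape} does not match network size {cpan.n_proteins}"
        )
    me_c = float(np.linalg.norm(z - cpan.matrix @ z))
    me_n = float(np.linalg.norm(z - npan.matrix @ z))
    return me_c, me_n


def align_query(x: ExpressionMatrix, proteins: list[str]) -> np.ndarray:
    """Rows of ``x`` aligned to ``proteins`` (K × samples).

    Network proteins absent from the query cohort are filled with 0 (the
    z-score mean) and logged; query genes outside the network are ignored.
    """
    row = x.row_index()
    out = np.zeros((len(proteins), x.n_samples))
    missing = []
    for i, p in enumerate(proteins):
        j = row.get(p)
        if j is None:
            missing.append(p)
        else:
            out[i] = x.values[j]
    if missing:
        logger.info(
            "align_query: %d network protein(s) absent from query; imputed 0: %s",
            len(missing), ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    return out


def classify(
    x: ExpressionMatrix, cpan: AssociationNetwork, npan: AssociationNetwork
) -> list[DiagnosisRecord]:
    """Classify every sample of a z-scored cohort by mapping-error comparison."""
    if x.n_samples == 0:
        raise ContractError("empty query cohort")
    if not x.normalized:
        raise ContractError("query cohort must be z-scored before classification")
    if cpan.proteins != npan.proteins:
        raise ContractError("networks disagree on protein lists")
    zmat = align_query(x, cpan.proteins)
    records = []
    for j, sid in enumerate(x.sample_ids):
        z = zmat[:, j]
        me_c, me_n = mapping_errors(z, cpan, npan)
        if me_c == me_n:
            logger.warning("classify: tie mapping errors for sample %s; assigning noncancer", sid)
            predicted = NONCANCER
        else:
            predicted = CANCER if me_c < me_n else NONCANCER
        truth = x.labels[j] if x.labels is not None else None
        records.append(DiagnosisRecord(sid, z, me_c, me_n, predicted, truth))
    return records


def evaluate(records: list[DiagnosisRecord]) -> PerformanceSummary:
    """Confusion counts and percentage metrics; cancer is the positive class."""
    if not records:
        raise ContractError("no records to evaluate")
    if any(r.truth is None for r in records):
        raise ContractError("every record needs a truth label")
    tp = sum(1 for r in records if r.truth == CANCER and r.predicted == CANCER)
    fn = sum(1 for r in records if r.truth == CANCER and r.predicted == NONCANCER)
    tn = sum(1 for r in records if r.truth == NONCANCER and r.predicted == NONCANCER)
    fp = sum(1 for r in records if r.truth == NONCANCER and r.predicted == CANCER)
    n = len(records)
    return PerformanceSummary(
        n=n, tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
    )


def summary_from_counts(tp: int, fn: int, tn: int, fp: int) -> PerformanceSummary:
    n = tp + fn + tn + fp
    if n == 0:
        raise ContractError("empty confusion table")
    return PerformanceSummary(
        n=n, tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
    )


def _fit_pair(rough, x_norm, t_alpha):
    cpan = build_association_network(rough, x_norm, CANCER, t_alpha)
    npan = build_association_network(rough, x_norm, NONCANCER, t_alpha)
    return cpan, npan


def random_network_baseline(
    pool_size: int,
    universe: list[str],
    ppi: InteractionSet,
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    reps: int = 100,
    seed: int = 0,
    t_alpha: float = 0.05,
) -> float:
    """Mean test accuracy (%) over randomly sampled protein pools.

    Per replicate, ``pool_size`` proteins are drawn uniformly from the
    universe, networks are fitted on the training cohort and the test
    cohort is classified.  Replicates whose sampled pool yields no network
    fall back to the all-noncancer prediction.
    """
    if reps < 1:
        raise ContractError("reps must be >= 1")
    universe = sorted({u.upper() for u in universe})
    if pool_size > len(universe):
        raise ContractError(f"pool_size {pool_size} exceeds universe of {len(universe)}")
    if test.labels is None:
        raise ContractError("test cohort needs truth labels")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(reps):
        sample = sorted(rng.choice(universe, size=pool_size, replace=False))
        try:
            rough = build_rough_network(sample, ppi, train)
            cpan, npan = _fit_pair(rough, train, t_alpha)
            records = classify(test, cpan, npan)
            acc = evaluate(records).accuracy
        except PipelineError:
            # degenerate pool: no edges at all -> every sample defaults to
            # noncancer under the tie rule
            acc = 100.0 * sum(1 for l in test.labels if l == NONCANCER) / test.n_samples
        accs.append(acc)
    return float(np.mean(accs))


def cross_validate(
    x: ExpressionMatrix,
    ppi: InteractionSet,
    folds: int = 5,
    seed: int = 0,
    de_alpha: float = 0.05,
    neighbor_threshold: int = 3,
    t_alpha: float = 0.05,
) -> tuple[list[PerformanceSummary], PerformanceSummary]:
    """Stratified k-fold cross-validation of the full pipeline.

    ``x`` is the raw (un-normalized) labeled cohort.  Training and test
    folds are z-scored separately; the pool, rough network and both
    association networks are re-derived per fold from training samples
    only.  Returns per-fold summaries plus one summary pooled over folds.
    """
    from .pipeline import train_networks  # local import to avoid a cycle

    if x.labels is None:
        raise ContractError("cross_validate requires labels")
    if folds < 2 or folds > x.n_samples:
        raise ContractError(f"folds must be in [2, {x.n_samples}]")
    y = np.array(x.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    summaries = []
    tp = fn = tn = fp = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        x_train = znormalize(x.subset_columns(train_idx))
        x_test = znormalize(x.subset_columns(test_idx))
        model = train_networks(
            x_train, ppi,
            de_alpha=de_alpha, neighbor_threshold=neighbor_threshold, t_alpha=t_alpha,
        )
        records = classify(x_test, model.cpan, model.npan)
        s = evaluate(records)
        summaries.append(s)
        tp += s.tp; fn += s.fn; tn += s.tn; fp += s.fp
    return summaries, summary_from_counts(tp, fn, tn, fp)


def cohort_similarity(x: ExpressionMatrix) -> tuple[float, float, float]:
    """Mean pairwise Pearson correlation of sample expression profiles.

    Returns (mean within cancer, mean within noncancer, mean over all
    pooled sample pairs).
    """
    if x.labels is None:
        raise ContractError("cohort_similarity requires labels")
    sizes = x.group_sizes()
    if min(sizes.values()) < 2:
        raise ContractError(f"each group needs >= 2 samples, got {sizes}")

    def mean_offdiag(mat: np.ndarray) -> float:
        corr = np.corrcoef(mat.T)
        iu = np.triu_indices(corr.shape[0], 1)
        return float(corr[iu].mean())

    r_c = mean_offdiag(x.values[:, x.group_indices(CANCER)])
    r_n = mean_offdiag(x.values[:, x.group_indices(NONCANCER)])
    r_all = mean_offdiag(x.values)
    return r_c, r_n, r_all
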