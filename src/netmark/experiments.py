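"""Seeded synthetic-data experiments used by the test suite and the
acceptance report.

Each experiment generates its own ground truth and cohorts, runs the
relevant pipeline stage(s) from scratch, and returns plain numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnosis import classify, evaluate
from .expression import CANCER, NONCANCER, znormalize
from .inference import build_association_network
from .scoring import compute_crv, difference_matrix, permutation_null
from .synthetic import combine_cohorts, generate_network_pair, simulate_expression


def _restrict(matrix: np.ndarray, proteins: list[str], subset: list[str]) -> np.ndarray:
    idx = [proteins.index(p) for p in subset]
    return matrix[np.ix_(idx, idx)]


def fit_pair_on_truth(truth, n_per_group: int, noise_sd: float, seed: int, t_alpha: float = 0.05):
    """Simulate both cohorts and fit both networks on the true rough graph."""
    xc = simulate_expression(truth, CANCER, n_per_group, noise_sd, seed + 1)
    xn = simulate_expression(truth, NONCANCER, n_per_group, noise_sd, seed + 2)
    x = znormalize(combine_cohorts(xc, xn))
    rough = truth.rough_true
    cpan = build_association_network(rough, x, CANCER, t_alpha)
    npan = build_association_network(rough, x, NONCANCER, t_alpha)
    return rough, cpan, npan


@dataclass
class RecoveryResult:
    median_abs_error: float
    f1: float
    precision: float
    recall: float


def recovery_experiment(
    seed: int,
    K: int = 50,
    n_edges: int = 100,
    shared_fraction: float = 0.7,
    n_per_group: int = 150,
    noise_sd: float = 0.1,
) -> RecoveryResult:
    """Parameter/support recovery of the true networks from simulated data.

    Pools both phenotypes: errors are measured over all true-edge positions
    of both generating matrices; support recovery compares fitted nonzero
    patterns against true edges.
    """
    truth = generate_network_pair(K, n_edges, shared_fraction, seed=seed)
    rough, cpan, npan = fit_pair_on_truth(truth, n_per_group, noise_sd, seed)
    sub = rough.proteins

    errs: list[float] = []
    tp = fp = fn = 0
    for est, true_net in ((cpan, truth.cpan_true), (npan, truth.npan_true)):
        t = _restrict(true_net.matrix, truth.proteins, sub)
        e = est.matrix
        iu = np.triu_indices(len(sub), 1)
        true_mask = t[iu] != 0
        est_mask = e[iu] != 0
        errs.extend(np.abs(e[iu][true_mask] - t[iu][true_mask]))
        tp += int(np.sum(true_mask & est_mask))
        fp += int(np.sum(~true_mask & est_mask))
        fn += int(np.sum(true_mask & ~est_mask))

    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return RecoveryResult(float(np.median(errs)), f1, precision, recall)


def calibration_experiment(
    seeds: list[int],
    K: int = 50,
    n_edges: int = 100,
    n_per_group: int = 150,
    noise_sd: float = 0.1,
    n_permutations: int = 1000,
) -> tuple[float, int]:
    """Fraction of proteins called significant under identical generators.

    With shared_fraction = 1 the two cohorts are drawn from the same
    network, so every p-value is a null draw; returns the pooled fraction
    with p <= 0.05 and the number of protein-tests pooled.
    """
    n_sig = 0
    n_tot = 0
    for seed in seeds:
        truth = generate_network_pair(K, n_edges, 1.0, seed=seed)
        rough, cpan, npan = fit_pair_on_truth(truth, n_per_group, noise_sd, seed)
        d = difference_matrix(cpan, npan)
        table = permutation_null(rough, d, n_permutations=n_permutations, seed=seed + 7)
        n_sig += int((table.table["p_value"] <= 0.05).sum())
        n_tot += len(table.table)
    return n_sig / n_tot, n_tot


def classification_experiment(
    seeds: list[int],
    shared_fraction: float,
    K: int = 50,
    n_edges: int = 100,
    n_train: int = 100,
    n_test: int = 20,
    noise_sd: float = 0.1,
) -> float:
    """Pooled held-out accuracy (%) over seeds for one overlap setting."""
    correct = 0
    total = 0
    for seed in seeds:
        truth = generate_network_pair(K, n_edges, shared_fraction, seed=seed)
        rough, cpan, npan = fit_pair_on_truth(truth, n_train, noise_sd, seed)
        tc = simulate_expression(truth, CANCER, n_test, noise_sd, seed + 11)
        tn = simulate_expression(truth, NONCANCER, n_test, noise_sd, seed + 12)
        test = znormalize(combine_cohorts(tc, tn))
        records = classify(test, cpan, npan)
        s = evaluate(records)
        correct += s.tp + s.tn
        total += s.n
    return 100.0 * correct / total


def identifiability_experiment(
    seeds: list[int],
    K: int = 50,
    n_edges: int = 100,
    shared_fraction: float = 0.7,
    n_per_group: int = 150,
    noise_sd: float = 0.1,
    top: int = 10,
) -> float:
    """Fraction of top-CRV proteins incident to a truly differing edge."""
    hits = 0
    total = 0
    for seed in seeds:
        truth = generate_network_pair(K, n_edges, shared_fraction, seed=seed)
        rough, cpan, npan = fit_pair_on_truth(truth, n_per_group, noise_sd, seed)
        d = difference_matrix(cpan, npan)
        crv = compute_crv(d)
        order = np.argsort(-crv, kind="stable")[:top]
        differing = truth.differing_proteins()
        for i in order:
            hits += d.proteins[i] in differing
            total += 1
    return hits / total
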