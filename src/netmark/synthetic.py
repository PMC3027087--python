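"""Ground-truth network pairs and model-consistent synthetic cohorts.

The generative law is the conditional-autoregression reading of the
association model: with a symmetric coefficient matrix ``A`` of spectral
radius < 1, samples are drawn from ``N(0, noise_sd^2 (I - A)^-1)``.  This
satisfies ``Y = A Y + E`` with ``Cov(E, Y) = noise_sd^2 I``: each
equation's noise is exactly uncorrelated with that target's regressors, so
the population regression coefficient of a protein on its neighbors equals
its row of ``A`` and the fitted networks are consistent estimates of the
truth.  (The naive fixed-point draw ``(I - A)^-1 e`` has covariance
``(I - A)^-2`` instead, which makes the regression estimand roughly twice
the generating coefficient.)

Two matrices sharing a configurable fraction of edges (position and
weight) play the roles of the cancer and non-cancer networks; an optional
raw-mean shift on proteins touching the differing edges makes the
differential-expression stage of the pipeline exercisable on synthetic
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ContractError
from .expression import CANCER, NONCANCER, ExpressionMatrix
from .inference import AssociationNetwork
from .pool import RoughNetwork

logger = logging.getLogger(__name__)

SPECTRAL_TARGET = 0.8


def _protein_names(k: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, k + 1)]


@dataclass
class GroundTruth:
    """True generating networks plus the parameters that made them."""

    cpan_true: AssociationNetwork
    npan_true: AssociationNetwork
    rough_true: RoughNetwork
    params: dict = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return self.cpan_true.proteins

    def differing_edges(self) -> set[tuple[int, int]]:
        """Index pairs (i < j) where the two true matrices differ."""
        diff = self.cpan_true.matrix != self.npan_true.matrix
        return {(i, j) for i, j in zip(*np.nonzero(np.triu(diff, 1)))}

    def differing_proteins(self) -> set[str]:
        prots = self.proteins
        out = set()
        for i, j in self.differing_edges():
            out.add(prots[i])
            out.add(prots[j])
        return out


def generate_network_pair(
    K: int,
    n_edges: int,
    shared_fraction: float,
    weight_low: float = 0.5,
    weight_high: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Sample two partially overlapping sparse symmetric coefficient matrices.

    ``n_edges`` distinct pairs get weights uniform in ±[weight_low,
    weight_high]; a ``shared_fraction`` subset (position and weight) is
    copied into the second matrix and the remainder resampled.  Both
    matrices are rescaled by a common factor so the larger spectral radius
    equals ``0.8`` (a shared factor keeps the shared edges identical).
    """
    max_edges = K * (K - 1) // 2
    if not 0 < n_edges <= max_edges:
        raise ContractError(f"n_edges must be in [1, {max_edges}]")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ContractError("shared_fraction must be in [0, 1]")
    if not 0.0 < weight_low <= weight_high:
        raise ContractError("need 0 < weight_low <= weight_high")

    rng = np.random.default_rng(seed)
    proteins = _protein_names(K)
    iu, ju = np.triu_indices(K, 1)

    def sample_weights(n):
        mags = rng.uniform(weight_low, weight_high, size=n)
        signs = rng.choice([-1.0, 1.0], size=n)
        return mags * signs

    first = rng.choice(max_edges, size=n_edges, replace=False)
    w_first = sample_weights(n_edges)

    n_shared = int(round(shared_fraction * n_edges))
    shared_sel = rng.permutation(n_edges)[:n_shared]
    shared_pairs = first[shared_sel]
    shared_w = w_first[shared_sel]

    taken = set(shared_pairs.tolist())
    free = np.array([p for p in range(max_edges) if p not in taken])
    n_new = n_edges - n_shared
    new_pairs = rng.choice(free, size=n_new, replace=False) if n_new else np.empty(0, dtype=int)
    w_new = sample_weights(n_new)

    a1 = np.zeros((K, K))
    a1[iu[first], ju[first]] = w_first
    a2 = np.zeros((K, K))
    a2[iu[shared_pairs], ju[shared_pairs]] = shared_w
    if n_new:
        a2[iu[new_pairs], ju[new_pairs]] = w_new
    a1 = a1 + a1.T
    a2 = a2 + a2.T

    rho = max(
        float(np.max(np.abs(np.linalg.eigvalsh(a1)))),
        float(np.max(np.abs(np.linalg.eigvalsh(a2)))),
    )
    if rho > 0:
        scale = SPECTRAL_TARGET / rho
        a1 *= scale
        a2 *= scale

    union = (a1 != 0) | (a2 != 0)
    g = nx.Graph()
    for i, j in zip(*np.nonzero(np.triu(union, 1))):
        g.add_edge(proteins[i], proteins[j])
    if g.number_of_nodes() == 0:
        raise ContractError("generated networks have no edges")
    rough = RoughNetwork(
        proteins=sorted(g.nodes),
        graph=g,
        degree_cap=max(dict(g.degree).values()) + 1,
    )

    params = {
        "K": K,
        "n_edges": n_edges,
        "shared_fraction": shared_fraction,
        "weight_low": weight_low,
        "weight_high": weight_high,
        "seed": seed,
    }
    return GroundTruth(
        cpan_true=AssociationNetwork(proteins, a1, CANCER),
        npan_true=AssociationNetwork(proteins, a2, NONCANCER),
        rough_true=rough,
        params=params,
    )


def simulate_expression(
    truth: GroundTruth,
    group: str,
    n: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    mean_shift: float = 0.0,
) -> ExpressionMatrix:
    """Draw ``n`` samples from the association model of one group.

    Samples are ``N(0, noise_sd^2 (I - A)^-1)``, realized as
    ``L^-T e`` with ``L L^T`` the Cholesky factorization of ``I - A`` and
    ``e`` i.i.d. Gaussian of standard deviation ``noise_sd``.  When
    ``mean_shift`` is nonzero and the group is cancer, proteins incident to
    a differing edge receive a raw mean offset so that downstream
    differential testing has signal.  Returned un-normalized.
    """
    if group not in (CANCER, NONCANCER):
        raise ContractError(f"unknown group {group!r}")
    if n < 2:
        raise ContractError("need n >= 2 samples")
    net = truth.cpan_true if group == CANCER else truth.npan_true
    A = net.matrix
    rho = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    if rho >= 1.0:
        raise ContractError(f"spectral radius {rho:.3f} >= 1; I - A is not positive definite")

    rng = np.random.default_rng(seed)
    k = A.shape[0]
    noise = rng.normal(0.0, noise_sd, size=(k, n))
    chol = np.linalg.cholesky(np.eye(k) - A)
    values = np.linalg.solve(chol.T, noise)

    if mean_shift != 0.0 and group == CANCER:
        shifted = truth.differing_proteins()
        ridx = [i for i, p in enumerate(truth.proteins) if p in shifted]
        values[ridx, :] += mean_shift

    prefix = "C" if group == CANCER else "N"
    return ExpressionMatrix(
        entity_ids=list(truth.proteins),
        sample_ids=[f"{prefix}{i:04d}" for i in range(1, n + 1)],
        values=values,
        labels=[group] * n,
        normalized=False,
    )


def combine_cohorts(*cohorts: ExpressionMatrix) -> ExpressionMatrix:
    """Concatenate cohorts sharing the same entity rows."""
    first = cohorts[0]
    for c in cohorts[1:]:
        if c.entity_ids != first.entity_ids:
            raise ContractError("cohorts disagree on entity rows")
    return ExpressionMatrix(
        entity_ids=list(first.entity_ids),
        sample_ids=[s for c in cohorts for s in c.sample_ids],
        values=np.concatenate([c.values for c in cohorts], axis=1),
        labels=(
            None
            if any(c.labels is None for c in cohorts)
            else [l for c in cohorts for l in c.labels]
        ),
        normalized=False,
    )


def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_fixture(
    truth: GroundTruth,
    cohorts: list[ExpressionMatrix],
    out_dir,
    decoy_fraction: float = 0.3,
) -> dict[str, Path]:
    """Write a file bundle in exactly the formats the ingest module reads.

    Produces ``expression.tsv``, ``labels.tsv``, ``ppi_edges.tsv`` (true
    union edges plus a seeded fraction of decoy non-edges), the two truth
    edge lists and a key-value ``manifest.txt``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x = combine_cohorts(*cohorts)

    expr_path = out_dir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("symbol\t" + "\t".join(x.sample_ids) + "\n")
        for i, e in enumerate(x.entity_ids):
            fh.write(e + "\t" + "\t".join(_fmt(v) for v in x.values[i]) + "\n")

    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w") as fh:
        for s, l in zip(x.sample_ids, x.labels):
            fh.write(f"{s}\t{l}\n")

    proteins = truth.proteins
    k = len(proteins)
    iu, ju = np.triu_indices(k, 1)
    union = (truth.cpan_true.matrix != 0) | (truth.npan_true.matrix != 0)
    true_flat = np.nonzero(union[iu, ju])[0]
    n_decoys = int(round(decoy_fraction * len(true_flat)))
    rng = np.random.default_rng(int(truth.params.get("seed", 0)) + 977)
    non_edges = np.nonzero(~union[iu, ju])[0]
    decoys = (
        rng.choice(non_edges, size=min(n_decoys, len(non_edges)), replace=False)
        if n_decoys
        else np.empty(0, dtype=int)
    )
    ppi_path = out_dir / "ppi_edges.tsv"
    all_flat = sorted(set(true_flat.tolist()) | set(decoys.tolist()))
    with open(ppi_path, "w") as fh:
        for f in all_flat:
            fh.write(f"{proteins[iu[f]]}\t{proteins[ju[f]]}\n")

    def write_truth(net: AssociationNetwork, path: Path):
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\talpha\n")
            for a, b, w in net.edge_list():
                fh.write(f"{a}\t{b}\t{_fmt(w)}\n")

    cpan_path = out_dir / "truth_cpan.tsv"
    npan_path = out_dir / "truth_npan.tsv"
    write_truth(truth.cpan_true, cpan_path)
    write_truth(truth.npan_true, npan_path)

    manifest_path = out_dir / "manifest.txt"
    with open(manifest_path, "w") as fh:
        for key, val in sorted(truth.params.items()):
            fh.write(f"{key}={val}\n")
        fh.write(f"decoy_fraction={decoy_fraction}\n")
        fh.write(f"n_true_edges={len(true_flat)}\n")
        fh.write(f"n_decoy_edges={len(decoys)}\n")
        fh.write(f"n_samples={x.n_samples}\n")

    return {
        "expression": expr_path,
        "labels": labels_path,
        "ppi": ppi_path,
        "truth_cpan": cpan_path,
        "truth_npan": npan_path,
        "manifest": manifest_path,
    }


def generate_fixture(
    out_dir,
    K: int = 50,
    n_edges: int = 100,
    shared_fraction: float = 0.7,
    weight_low: float = 0.5,
    weight_high: float = 1.0,
    noise_sd: float = 0.1,
    n_cancer: int = 150,
    n_noncancer: int = 150,
    mean_shift: float = 0.0,
    decoy_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[GroundTruth, dict[str, Path]]:
    """One-call fixture bundle: network pair + cohorts + files on disk."""
    truth = generate_network_pair(K, n_edges, shared_fraction, weight_low, weight_high, seed)
    truth.params.update(
        noise_sd=noise_sd, n_cancer=n_cancer, n_noncancer=n_noncancer, mean_shift=mean_shift
    )
    xc = simulate_expression(truth, CANCER, n_cancer, noise_sd, seed + 1, mean_shift)
    xn = simulate_expression(truth, NONCANCER, n_noncancer, noise_sd, seed + 2)
    paths = write_fixture(truth, [xc, xn], out_dir, decoy_fraction)
    return truth, paths
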