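"""End-to-end training helper and plain-text artifact writers.

Everything the CLI writes lives here so that library users and tests can
produce (and byte-compare) the same tables without going through click.
All writers use fixed float formatting and sorted, deterministic ordering:
a rerun with the same config and seed reproduces identical bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diagnosis import DiagnosisRecord, PerformanceSummary
from .expression import CANCER, NONCANCER, ExpressionMatrix
from .inference import AssociationNetwork, build_association_network
from .interactions import InteractionSet
from .pool import DifferentialTable, RoughNetwork, build_rough_network, differential_test, select_pool
from .scoring import CRVTable, DifferenceMatrix

logger = logging.getLogger(__name__)

# full round-trip precision so that stages resumed from written artifacts
# reproduce in-memory results bit-for-bit
FLOAT_FMT = "%.17g"


def _f(v: float) -> str:
    return FLOAT_FMT % v


@dataclass
class NetworkBiomarker:
    """Everything produced by training on one labeled cohort."""

    differential: DifferentialTable
    pool: list[str]
    rough: RoughNetwork
    cpan: AssociationNetwork
    npan: AssociationNetwork


def train_networks(
    x_norm: ExpressionMatrix,
    ppi: InteractionSet,
    de_alpha: float = 0.05,
    neighbor_threshold: int = 3,
    t_alpha: float = 0.05,
) -> NetworkBiomarker:
    """Differential pool -> rough network -> both association networks."""
    dt = differential_test(x_norm, alpha=de_alpha, ppi=ppi)
    pool = select_pool(dt, ppi, alpha=de_alpha, neighbor_threshold=neighbor_threshold)
    rough = build_rough_network(pool, ppi, x_norm)
    cpan = build_association_network(rough, x_norm, CANCER, t_alpha)
    npan = build_association_network(rough, x_norm, NONCANCER, t_alpha)
    return NetworkBiomarker(differential=dt, pool=pool, rough=rough, cpan=cpan, npan=npan)


# -- writers --------------------------------------------------------------


def write_differential_tsv(dt: DifferentialTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tf_statistic\tp_raw\tp_bonferroni\tselected\n")
        for row in dt.table.itertuples(index=False):
            fh.write(
                f"{row.protein}\t{_f(row.f_statistic)}\t{_f(row.p_raw)}\t"
                f"{_f(row.p_bonferroni)}\t{int(row.selected)}\n"
            )


def write_pool(pool: list[str], path) -> None:
    with open(path, "w") as fh:
        for p in pool:
            fh.write(p + "\n")


def write_rough_network(rough: RoughNetwork, edges_path, proteins_path) -> None:
    with open(edges_path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in rough.edges():
            fh.write(f"{a}\t{b}\n")
    with open(proteins_path, "w") as fh:
        for p in rough.proteins:
            fh.write(p + "\n")


def read_rough_network(edges_path, proteins_path, degree_cap: int) -> RoughNetwork:
    import networkx as nx

    proteins = [l.strip() for l in open(proteins_path) if l.strip()]
    g = nx.Graph()
    g.add_nodes_from(proteins)
    with open(edges_path) as fh:
        next(fh)  # header
        for line in fh:
            a, b = line.rstrip("\n").split("\t")[:2]
            g.add_edge(a, b)
    return RoughNetwork(proteins=proteins, graph=g, degree_cap=degree_cap)


def write_association_tsv(net: AssociationNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\talpha\n")
        for a, b, w in net.edge_list():
            fh.write(f"{a}\t{b}\t{_f(w)}\n")


def write_sif(edges: list[tuple[str, str, float]], path, relation: str = "assoc") -> None:
    """Simple interaction format for network viewers."""
    with open(path, "w") as fh:
        for a, b, _ in sorted(edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_association_tsv(path, proteins: list[str], phenotype: str) -> AssociationNetwork:
    idx = {p: i for i, p in enumerate(proteins)}
    mat = np.zeros((len(proteins), len(proteins)))
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")[:3]
            i, j = idx[a], idx[b]
            mat[i, j] = mat[j, i] = float(w)
    return AssociationNetwork(proteins=proteins, matrix=mat, phenotype=phenotype)


def write_fit_audit(cpan: AssociationNetwork, npan: AssociationNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("phenotype\ttarget\tneighbor\talpha\tse\tt\tstatus\tstage\n")
        for net in (cpan, npan):
            if not net.fits:
                continue
            for target in sorted(net.fits):
                fit = net.fits[target]
                for q, a, se, t in zip(fit.neighbors, fit.alpha_hat, fit.se, fit.t_stat):
                    fh.write(
                        f"{net.phenotype}\t{target}\t{q}\t{_f(a)}\t{_f(se)}\t{_f(t)}\tkept\tfinal\n"
                    )
                for q, stage in fit.dropped:
                    fh.write(f"{net.phenotype}\t{target}\t{q}\tNA\tNA\tNA\tdropped\t{stage}\n")


def write_crv_tsv(t: CRVTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tcrv\tp_value\tsignificant\n")
        for row in t.table.itertuples(index=False):
            fh.write(f"{row.protein}\t{_f(row.crv)}\t{row.p_label}\t{int(row.significant)}\n")


def write_difference_tsv(d: DifferenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\td\n")
        for i, j in zip(*np.nonzero(np.triu(d.matrix, 1))):
            fh.write(f"{d.proteins[i]}\t{d.proteins[j]}\t{_f(d.matrix[i, j])}\n")


def write_diagnosis_tsv(records: list[DiagnosisRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tme_c\tme_n\tpredicted\ttruth\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{_f(r.me_c)}\t{_f(r.me_n)}\t{r.predicted}\t"
                f"{r.truth if r.truth is not None else 'NA'}\n"
            )


def read_diagnosis_tsv(path) -> list[DiagnosisRecord]:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            sid, me_c, me_n, pred, truth = line.rstrip("\n").split("\t")[:5]
            records.append(
                DiagnosisRecord(
                    sample_id=sid,
                    z=np.empty(0),
                    me_c=float(me_c),
                    me_n=float(me_n),
                    predicted=pred,
                    truth=None if truth == "NA" else truth,
                )
            )
    return records


def write_metrics_json(summary: PerformanceSummary, path) -> None:
    payload = {
        "n": summary.n,
        "tp": summary.tp,
        "tn": summary.tn,
        "fp": summary.fp,
        "fn": summary.fn,
        "accuracy": round(summary.accuracy, 4),
        "sensitivity": round(summary.sensitivity, 4),
        "specificity": round(summary.specificity, 4),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(entries: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")
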