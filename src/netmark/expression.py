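"""Expression-matrix ingest and normalization.

The central data carrier is :class:`ExpressionMatrix`: a genes/proteins ×
samples matrix with optional per-sample phenotype labels.  All downstream
modelling assumes rows have been z-scored (mean 0, sd 1 across samples),
which :func:`znormalize` performs; rows that cannot be normalized
(zero variance, missing values) are dropped and logged, never imputed.

Protein/gene symbols are folded to upper case on ingest so that microarray
and interaction sources that disagree on case join correctly.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError

logger = logging.getLogger(__name__)

#: Recognized phenotype labels.
CANCER = "cancer"
NONCANCER = "noncancer"
PHENOTYPES = (CANCER, NONCANCER)


def _parse_float(s) -> float:
    try:
        return float(s)
    except (TypeError, ValueError):
        return float("nan")


def _open_text(path):
    """Open a (possibly gzipped) text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


@dataclass
class ExpressionMatrix:
    """A labelled entities × samples real matrix.

    Parameters
    ----------
    entity_ids
        Gene/protein symbols, one per row; unique.
    sample_ids
        Sample identifiers, one per column; unique.
    values
        Float matrix of shape ``(len(entity_ids), len(sample_ids))``.
    labels
        Optional per-sample phenotype, each in ``{"cancer", "noncancer"}``.
    normalized
        True once rows have been z-scored by :func:`znormalize`.
    """

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = list(self.entity_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ContractError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ContractError("entity_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ContractError("sample_ids are not unique")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.sample_ids):
                raise ContractError("labels length does not match sample count")
            bad = sorted({l for l in self.labels if l not in PHENOTYPES})
            if bad:
                raise ContractError(f"unknown phenotype labels: {bad}")

    # -- basic views ------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def group_indices(self, label: str) -> np.ndarray:
        """Column indices of samples carrying ``label``."""
        if self.labels is None:
            raise ContractError("matrix has no phenotype labels")
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)

    def group_sizes(self) -> dict[str, int]:
        if self.labels is None:
            raise ContractError("matrix has no phenotype labels")
        return {p: int(sum(l == p for l in self.labels)) for p in PHENOTYPES}

    def group_view(self, label: str) -> "ExpressionMatrix":
        """Sub-matrix restricted to the samples of one phenotype."""
        idx = self.group_indices(label)
        return ExpressionMatrix(
            entity_ids=list(self.entity_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=[self.labels[i] for i in idx],
            normalized=self.normalized,
        )

    def subset_columns(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            entity_ids=list(self.entity_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)


# -- readers --------------------------------------------------------------


def read_labels(path) -> dict[str, str]:
    """Read a two-column tab-delimited sample→phenotype file."""
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{ln}: expected two tab-separated columns: {line!r}")
            sid, lab = parts[0].strip(), parts[1].strip().lower()
            if lab not in PHENOTYPES:
                raise InputError(f"{path}:{ln}: unknown phenotype {lab!r} (want cancer/noncancer)")
            if sid in labels and labels[sid] != lab:
                raise InputError(f"{path}:{ln}: conflicting labels for sample {sid!r}")
            labels[sid] = lab
    if not labels:
        raise InputError(f"{path}: no labels found")
    return labels


def read_expression(matrix_path, labels_path=None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (entities × samples).

    The first row is a header of sample ids; the first column holds entity
    symbols.  Rows containing non-numeric or missing cells are dropped and
    logged.  Duplicate entity symbols (after upper-casing) are collapsed by
    the row mean of their raw values.
    """
    with _open_text(matrix_path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise InputError(f"{matrix_path}: empty or malformed header line")
        cols = header.split("\t")
        sample_ids = [c.strip() for c in cols[1:]]
        if not sample_ids or any(not s for s in sample_ids):
            raise InputError(f"{matrix_path}: malformed header: {header!r}")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise InputError(f"{matrix_path}: duplicate sample ids in header: {dupes}")

        symbols: list[str] = []
        rows: list[list[str]] = []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise InputError(
                    f"{matrix_path}:{ln}: expected {len(sample_ids) + 1} fields, got {len(parts)}"
                )
            symbols.append(parts[0].strip().upper())
            rows.append(parts[1:])

    if not rows:
        raise InputError(f"{matrix_path}: no data rows")

    raw = pd.DataFrame(rows, index=symbols, columns=sample_ids)
    # exact strtod parsing; pandas' to_numeric fast path is lossy in the
    # last ulp, which would break byte-level fixture round trips
    numeric = raw.map(_parse_float)
    bad = numeric.isna().any(axis=1)
    if bad.any():
        dropped = sorted(set(numeric.index[bad]))
        logger.warning(
            "read_expression: dropped %d row(s) with missing/non-numeric cells: %s",
            int(bad.sum()), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        numeric = numeric.loc[~bad]
    if numeric.empty:
        raise InputError(f"{matrix_path}: no numeric rows survive ingest")

    if numeric.index.has_duplicates:
        n_before = len(numeric)
        dup = sorted(set(numeric.index[numeric.index.duplicated()]))
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info(
            "read_expression: collapsed %d duplicate-symbol rows by mean (%s)",
            n_before - len(numeric), ", ".join(dup[:10]),
        )

    labels = None
    if labels_path is not None:
        table = read_labels(labels_path)
        unknown = sorted(set(table) - set(numeric.columns))
        if unknown:
            raise InputError(f"{labels_path}: labels for unknown samples: {unknown}")
        missing = sorted(set(numeric.columns) - set(table))
        if missing:
            raise InputError(f"{labels_path}: samples without a label: {missing}")
        labels = [table[s] for s in numeric.columns]

    return ExpressionMatrix(
        entity_ids=list(numeric.index),
        sample_ids=list(numeric.columns),
        values=numeric.to_numpy(dtype=float),
        labels=labels,
        normalized=False,
    )


def read_geo_series_matrix(path) -> ExpressionMatrix:
    """Read the expression table of a GEO series-matrix file (unlabelled)."""
    in_table = False
    header: list[str] | None = None
    symbols: list[str] = []
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.lower().startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if header is None:
                header = parts
            else:
                symbols.append(parts[0].upper())
                rows.append(parts[1:])
    if header is None or not rows:
        raise InputError(f"{path}: no series-matrix table found")
    frame = pd.DataFrame(rows, index=symbols, columns=header[1:])
    frame = frame.apply(pd.to_numeric, errors="coerce")
    keep = ~frame.isna().any(axis=1)
    if (~keep).any():
        logger.warning("read_geo_series_matrix: dropped %d rows with missing values", int((~keep).sum()))
    frame = frame.loc[keep]
    if frame.index.has_duplicates:
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        entity_ids=list(frame.index),
        sample_ids=list(frame.columns),
        values=frame.to_numpy(dtype=float),
    )


# -- transforms -----------------------------------------------------------


def row_stats(x: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and sample standard deviation of a raw matrix."""
    return x.values.mean(axis=1), x.values.std(axis=1, ddof=1)


def znormalize(
    x: ExpressionMatrix,
    mu: np.ndarray | None = None,
    sd: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Z-score every row: (g - mean) / sd over all samples of the matrix.

    Uses the sample standard deviation (ddof=1).  By default statistics
    come from ``x`` itself; pass ``mu``/``sd`` (e.g. from
    :func:`row_stats` of a training cohort, aligned to ``x.entity_ids``)
    to normalize a query cohort on training statistics instead.
    Zero-variance rows are removed with a warning.  Raises
    :class:`ContractError` if ``x`` is already normalized.
    """
    if x.normalized:
        raise ContractError("matrix is already normalized")
    if (mu is None) != (sd is None):
        raise ContractError("mu and sd must be supplied together")
    if mu is None:
        mu, sd = row_stats(x)
    else:
        mu = np.asarray(mu, dtype=float)
        sd = np.asarray(sd, dtype=float)
        if mu.shape != (x.n_entities,) or sd.shape != (x.n_entities,):
            raise ContractError("mu/sd length does not match entity count")
    keep = sd > 0.0
    if not keep.all():
        dropped = [e for e, k in zip(x.entity_ids, keep) if not k]
        logger.warning(
            "znormalize: removed %d zero-variance row(s): %s",
            len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not keep.any():
        raise ContractError("no rows with nonzero variance")
    vals = (x.values[keep] - mu[keep, None]) / sd[keep, None]
    return ExpressionMatrix(
        entity_ids=[e for e, k in zip(x.entity_ids, keep) if k],
        sample_ids=list(x.sample_ids),
        values=vals,
        labels=None if x.labels is None else list(x.labels),
        normalized=True,
    )


def read_gene_protein_mapping(path) -> dict[str, str]:
    """Read a two-column gene→protein symbol table (case-insensitive)."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{ln}: expected two tab-separated columns")
            gene, prot = parts[0].strip().upper(), parts[1].strip().upper()
            if gene in mapping and mapping[gene] != prot:
                raise InputError(f"{path}:{ln}: conflicting mapping for key {gene!r}")
            mapping[gene] = prot
    return mapping


def overlay_genes_on_proteins(
    x: ExpressionMatrix, mapping: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Re-key entity rows from gene to protein symbols.

    Genes mapping to the same protein are collapsed by the mean of their raw
    rows; unmapped genes are retained under their own (upper-cased) symbol.
    Must be applied before z-normalization so that collapsing happens on raw
    values.
    """
    if x.normalized:
        raise ContractError("overlay must be applied to un-normalized values")
    if mapping is None:
        mapping = {}
    else:
        folded: dict[str, str] = {}
        for k, v in mapping.items():
            ku, vu = str(k).upper(), str(v).upper()
            if ku in folded and folded[ku] != vu:
                raise InputError(f"conflicting mapping for key {ku!r}: {folded[ku]!r} vs {vu!r}")
            folded[ku] = vu
        mapping = folded

    targets = [mapping.get(e.upper(), e.upper()) for e in x.entity_ids]
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(targets):
        if t not in groups:
            groups[t] = []
            order.append(t)
        groups[t].append(i)

    n_collapsed = sum(1 for t in order if len(groups[t]) > 1)
    if n_collapsed:
        logger.info("overlay_genes_on_proteins: collapsed rows for %d protein(s) by mean", n_collapsed)
    unmapped = sorted({e.upper() for e in x.entity_ids if e.upper() not in mapping}) if mapping else []
    if mapping and unmapped:
        logger.info("overlay_genes_on_proteins: %d gene(s) retained without mapping", len(unmapped))

    vals = np.vstack([x.values[groups[t]].mean(axis=0) for t in order])
    return ExpressionMatrix(
        entity_ids=order,
        sample_ids=list(x.sample_ids),
        values=vals,
        labels=None if x.labels is None else list(x.labels),
        normalized=False,
    )
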