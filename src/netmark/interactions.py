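"""Protein-protein interaction ingest.

Supported dialects: BioGRID TAB2 (official-symbol columns), HPRD
tab-delimited flat files (symbols in columns 1 and 4), and generic
two-column edge lists.  All readers are gzip-transparent, fold symbols to
upper case, drop self-interactions, and merge duplicate pairs across
sources while keeping per-pair provenance tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InputError
from .expression import _open_text

logger = logging.getLogger(__name__)

DIALECTS = ("biogrid_tab2", "hprd", "edgelist")
_PROVENANCE = {"biogrid_tab2": "biogrid", "hprd": "hprd", "edgelist": "generic"}


def _canon(a: str, b: str) -> tuple[str, str]:
    a, b = a.strip().upper(), b.strip().upper()
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionSet:
    """A set of unordered protein-symbol pairs with provenance tags."""

    _pairs: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return _canon(a, b) in self._pairs

    def add(self, a: str, b: str, source: str = "generic") -> None:
        a, b = a.strip().upper(), b.strip().upper()
        if not a or not b or a == b:
            return
        self._pairs.setdefault(_canon(a, b), set()).add(source)

    def provenance(self, a: str, b: str) -> set[str]:
        return set(self._pairs.get(_canon(a, b), set()))

    def union(self, other: "InteractionSet") -> "InteractionSet":
        out = InteractionSet()
        for pairs in (self._pairs, other._pairs):
            for (a, b), tags in pairs.items():
                out._pairs.setdefault((a, b), set()).update(tags)
        return out

    def neighbors_map(self) -> dict[str, set[str]]:
        nbrs: dict[str, set[str]] = {}
        for a, b in self._pairs:
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        return nbrs

    def degree(self, symbol: str) -> int:
        symbol = symbol.upper()
        return sum(1 for a, b in self._pairs if a == symbol or b == symbol)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._pairs)


def _parse_biogrid_tab2(fh, path) -> Iterable[tuple[str, str]]:
    header = fh.readline().rstrip("\n")
    if not header:
        raise InputError(f"{path}: empty BioGRID file")
    cols = [c.strip().lstrip("#").strip().lower() for c in header.split("\t")]
    try:
        ia = cols.index("official symbol interactor a")
        ib = cols.index("official symbol interactor b")
    except ValueError:
        raise InputError(f"{path}: BioGRID TAB2 official-symbol columns not found in header")
    for line in fh:
        parts = line.rstrip("\n").split("\t")
        if len(parts) <= max(ia, ib):
            continue
        yield parts[ia], parts[ib]


def _parse_hprd(fh, path) -> Iterable[tuple[str, str]]:
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 4:
            yield parts[0], parts[3]
        elif len(parts) >= 2:
            yield parts[0], parts[1]


def _parse_edgelist(fh, path) -> Iterable[tuple[str, str]]:
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) >= 2:
            yield parts[0], parts[1]


_PARSERS = {
    "biogrid_tab2": _parse_biogrid_tab2,
    "hprd": _parse_hprd,
    "edgelist": _parse_edgelist,
}


def read_interactions(paths, dialect: str) -> InteractionSet:
    """Read one or more interaction files of a single dialect.

    Returns the union of all pairs with self-interactions removed and
    duplicates merged.  A file contributing no parseable pair is an error.
    """
    if dialect not in DIALECTS:
        raise InputError(f"unknown PPI dialect {dialect!r}; expected one of {DIALECTS}")
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    out = InteractionSet()
    tag = _PROVENANCE[dialect]
    for path in paths:
        n_before = len(out)
        n_self = 0
        with _open_text(path) as fh:
            for a, b in _PARSERS[dialect](fh, path):
                if a.strip().upper() == b.strip().upper():
                    n_self += 1
                    continue
                out.add(a, b, tag)
        if len(out) == n_before and n_self == 0:
            raise InputError(f"{path}: no parseable interaction pairs under dialect {dialect!r}")
        if n_self:
            logger.info("read_interactions: %s: dropped %d self-interaction(s)", path, n_self)
    if not len(out):
        raise InputError("no interaction pairs parsed from any input file")
    return out


def load_interactions(specs) -> InteractionSet:
    """Merge several (path, dialect) sources into one InteractionSet."""
    out = InteractionSet()
    for path, dialect in specs:
        out = out.union(read_interactions([path], dialect))
    return out
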