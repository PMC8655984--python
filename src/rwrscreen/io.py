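"""Readers and writers for the formats the pipeline touches.

* STRING links text (``protein1 protein2 combined_score``, optionally gzipped)
* plain gene-list text (one identifier per line, ``#`` comments)
* GMT term -> gene-set annotations
* tab-separated screening results

Identifiers are opaque strings throughout; no Ensembl validation or ID
mapping is attempted.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import EmptyInputError, InputFormatError
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "AnnotationMap",
    "read_string_links",
    "read_gene_set",
    "restrict_to_network",
    "read_gmt",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class GeneSet:
    """Ordered, duplicate-free collection of gene identifiers."""

    identifiers: tuple[str, ...]
    label: str = ""

    @classmethod
    def from_iterable(cls, genes: Iterable[str], label: str = "") -> "GeneSet":
        seen: dict[str, None] = {}
        dups = 0
        for g in genes:
            if g in seen:
                dups += 1
            else:
                seen[g] = None
        if dups:
            logger.warning("gene set %r: dropped %d duplicate identifiers", label, dups)
        return cls(identifiers=tuple(seen), label=label)

    def __len__(self) -> int:
        return len(self.identifiers)

    def __iter__(self):
        return iter(self.identifiers)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.identifiers)


@dataclass(frozen=True)
class AnnotationMap:
    """Functional annotation: term id -> gene set, plus term descriptions.

    ``terms`` preserves file order; that order is the shared global term
    ordering used by every enrichment vector.
    """

    genes_by_term: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.genes_by_term)

    def __len__(self) -> int:
        return len(self.genes_by_term)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.genes_by_term[term]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_string_links(
    path: str | Path, min_score: float = 0.0
) -> list[tuple[str, str, float]]:
    """Parse a STRING links file into (protein1, protein2, score) rows.

    Whitespace-separated columns; a single header line starting with
    ``protein1`` is skipped.  Rows with score > ``min_score`` are returned in
    file order.  STRING lists each pair in both directions; deduplication is
    the job of :func:`rwrscreen.network.build_network`.
    """
    rows: list[tuple[str, str, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and line.startswith("protein1"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise InputFormatError(
                    f"expected 3 whitespace-separated columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            u, v, raw = fields
            try:
                score = float(raw)
            except ValueError:
                raise InputFormatError(
                    f"non-numeric combined_score {raw!r}",
                    path=str(path), line=lineno,
                ) from None
            if score > min_score:
                rows.append((u, v, score))
    if not rows:
        raise EmptyInputError(f"{path}: no interaction rows above score {min_score}")
    return rows


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a one-identifier-per-line gene list; ``#`` lines are comments."""
    genes: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line)
    if not genes:
        raise EmptyInputError(f"{path}: gene list is empty")
    return GeneSet.from_iterable(genes, label=label if label is not None else str(path))


def restrict_to_network(genes: GeneSet, net: PPINetwork) -> GeneSet:
    """Keep only identifiers present in the network, preserving input order."""
    kept = [g for g in genes if g in net]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info(
            "gene set %r: excluded %d of %d identifiers not in the network",
            genes.label, dropped, len(genes),
        )
    if not kept:
        raise EmptyInputError(
            f"gene set {genes.label!r}: no identifier is present in the network"
        )
    return GeneSet(identifiers=tuple(kept), label=genes.label)


def read_gmt(path: str | Path) -> AnnotationMap:
    """Read GMT annotations: ``term<TAB>description<TAB>gene1<TAB>gene2...``."""
    genes_by_term: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputFormatError(
                    "GMT row needs at least term<TAB>description",
                    path=str(path), line=lineno,
                )
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                logger.warning("%s:%d: term %r has no genes; dropped", path, lineno, term)
                continue
            genes_by_term[term] = frozenset(genes)
            descriptions[term] = desc
    if not genes_by_term:
        raise EmptyInputError(f"{path}: no usable terms")
    return AnnotationMap(genes_by_term=genes_by_term, descriptions=descriptions)


_RESULT_COLUMNS = (
    "gene", "probability", "z_score", "mls", "mes",
    "pass_permutation", "pass_linkage", "pass_enrichment", "inferred",
)


def _fmt_float(x: float | None) -> str:
    if x is None:
        return "NA"
    return repr(float(x))


def _fmt_flag(x: bool | None) -> str:
    if x is None:
        return "NA"
    return "1" if x else "0"


def write_results(path: str | Path, records: Sequence) -> None:
    """Write screening records as TSV, sorted by descending MES then gene id.

    Floats are written at full ``repr`` precision so the file round-trips
    losslessly; lazily skipped scores appear as ``NA``.
    """

    def sort_key(rec):
        mes = rec.mes if rec.mes is not None else -math.inf
        return (-mes, rec.gene)

    with open(path, "wt") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for rec in sorted(records, key=sort_key):
            fh.write(
                "\t".join(
                    (
                        rec.gene,
                        _fmt_float(rec.probability),
                        _fmt_float(rec.z_score),
                        _fmt_float(rec.mls),
                        _fmt_float(rec.mes),
                        _fmt_flag(rec.pass_permutation),
                        _fmt_flag(rec.pass_linkage),
                        _fmt_flag(rec.pass_enrichment),
                        _fmt_flag(rec.inferred),
                    )
                )
                + "\n"
            )


def read_results(path: str | Path) -> list:
    """Read back a results TSV written by :func:`write_results`."""
    from .screening import ScreeningRecord

    def parse_float(s: str) -> float | None:
        return None if s == "NA" else float(s)

    def parse_flag(s: str) -> bool | None:
        return None if s == "NA" else bool(int(s))

    records = []
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RESULT_COLUMNS:
            raise InputFormatError("unexpected results header", path=str(path), line=1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_RESULT_COLUMNS):
                raise InputFormatError(
                    f"expected {len(_RESULT_COLUMNS)} columns", path=str(path), line=lineno
                )
            records.append(
                ScreeningRecord(
                    gene=fields[0],
                    probability=parse_float(fields[1]),
                    z_score=parse_float(fields[2]),
                    mls=parse_float(fields[3]),
                    mes=parse_float(fields[4]),
                    pass_permutation=parse_flag(fields[5]),
                    pass_linkage=parse_flag(fields[6]),
                    pass_enrichment=parse_flag(fields[7]),
                    inferred=parse_flag(fields[8]),
                )
            )
    return records
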