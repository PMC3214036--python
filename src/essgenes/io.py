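"""Flat-file readers and writers plus the shared domain vocabulary.

Every file the pipeline touches is UTF-8, tab-separated text with a header
row; lines starting with ``!`` are comments (the GAF convention). Missing
optional fields are empty strings, never ``NA``. Identifiers are opaque,
case-sensitive strings — no symbol-to-accession resolution is attempted;
input files are assumed to use one namespace consistently.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

logger = logging.getLogger("essgenes")

INHERITANCE_MODES = ("AD", "AR", "X")
GENICITIES = ("monogenic", "polygenic", "unknown")
MECHANISM_LABELS = ("gain", "loss", "neutral")


class InputFormatError(ValueError):
    """A malformed input row; message names file, line, and column."""


@dataclass
class GeneRecord:
    """One human gene: ortholog, knockout phenotypes, disease/housekeeping flags."""

    gene_id: str
    symbol: str = ""
    mouse_ortholog: str = ""
    ko_phenotypes: frozenset[str] = frozenset()
    is_disease: bool = False
    is_housekeeping: bool = False


@dataclass
class GeneTable:
    """Per-gene joined view over orthology, phenotype, disease and housekeeping files."""

    records: dict[str, GeneRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records.values())

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records


@dataclass(frozen=True)
class DiseaseAssociation:
    """One gene–disease link with class, inheritance and genicity labels.

    A gene may appear in several rows, and its alleles may exhibit different
    inheritance patterns, so one gene can legitimately carry both AD and AR.
    """

    gene_id: str
    disease_id: str
    disease_class: str = ""
    inheritance_mode: str = ""  # one of AD | AR | X | ""
    genicity: str = ""  # monogenic | polygenic | ""
    mechanism_label: str = ""  # gain | loss | other | ""


@dataclass
class AnnotationTable:
    """gene_id -> set of term strings within one namespace."""

    namespace: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene_id: str, term: str) -> None:
        if not term:
            raise ValueError("empty term string")
        self.entries.setdefault(gene_id, set()).add(term)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.entries.values():
            out |= ts
        return out

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.entries.items() if term in ts}


@dataclass(frozen=True)
class EdgePair:
    a: str
    b: str
    source: str = ""


@dataclass
class EdgeList:
    """Raw interaction pairs, verbatim: duplicates and self-pairs retained.

    Cleaning (self-edge removal, deduplication) is the network module's job.
    """

    pairs: list[EdgePair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[EdgePair]:
        return iter(self.pairs)


@dataclass(frozen=True)
class TextRecord:
    """An OMIM-like free-text disease record, optionally with a known mechanism label."""

    record_id: str
    gene_id: str
    text: str
    known_label: Optional[str] = None  # gain | loss | neutral


# ---------------------------------------------------------------------------
# low-level TSV plumbing


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("!"):
                continue
            yield lineno, row


def _read_table(path: str | Path, required: Sequence[str]) -> Iterator[tuple[int, dict[str, str]]]:
    """Yield rows as dicts keyed by header; enforce required columns."""
    path = Path(path)
    it = _rows(path)
    try:
        _, header = next(it)
    except StopIteration:
        return
    missing = [c for c in required if c not in header]
    if missing:
        raise InputFormatError(f"{path}, line 1: missing column(s) {', '.join(missing)}")
    for lineno, row in it:
        if len(row) < len(required):
            raise InputFormatError(
                f"{path}, line {lineno}: expected at least {len(required)} fields, got {len(row)}"
            )
        yield lineno, {h: (row[i] if i < len(row) else "") for i, h in enumerate(header)}


def _require(value: str, path: Path, lineno: int, column: str) -> str:
    if not value.strip():
        raise InputFormatError(f"{path}, line {lineno}: empty value in column '{column}'")
    return value.strip()


# ---------------------------------------------------------------------------
# readers


def read_gene_table(
    orthology_path: str | Path,
    phenotypes_path: str | Path,
    disease_path: str | Path,
    housekeeping_path: str | Path,
) -> GeneTable:
    """Join the four gene-level inputs into one GeneTable.

    The gene universe is the union of human gene ids appearing in any file.
    Phenotype terms reach human genes through the orthology mapping; a gene
    with no knockout report keeps an empty phenotype set (that emptiness is
    what downstream classification reads as "unknown essentiality").
    """
    orthology_path = Path(orthology_path)
    ortho: dict[str, str] = {}
    for lineno, row in _read_table(orthology_path, ["human_gene_id", "mouse_gene_id"]):
        hg = _require(row["human_gene_id"], orthology_path, lineno, "human_gene_id")
        mg = _require(row["mouse_gene_id"], orthology_path, lineno, "mouse_gene_id")
        if hg in ortho:
            raise InputFormatError(f"{orthology_path}, line {lineno}: duplicate gene_id '{hg}'")
        ortho[hg] = mg

    phenotypes_path = Path(phenotypes_path)
    mouse_phen: dict[str, set[str]] = {}
    for lineno, row in _read_table(phenotypes_path, ["mouse_gene_id", "phenotype_term"]):
        mg = _require(row["mouse_gene_id"], phenotypes_path, lineno, "mouse_gene_id")
        term = _require(row["phenotype_term"], phenotypes_path, lineno, "phenotype_term")
        mouse_phen.setdefault(mg, set()).add(term)

    disease_genes = {a.gene_id for a in read_disease_associations(disease_path)}
    housekeeping = read_housekeeping_list(housekeeping_path)

    records: dict[str, GeneRecord] = {}
    universe = set(ortho) | disease_genes | housekeeping
    for gid in sorted(universe):
        mg = ortho.get(gid, "")
        records[gid] = GeneRecord(
            gene_id=gid,
            mouse_ortholog=mg,
            ko_phenotypes=frozenset(mouse_phen.get(mg, ())) if mg else frozenset(),
            is_disease=gid in disease_genes,
            is_housekeeping=gid in housekeeping,
        )
    return GeneTable(records)


def read_disease_associations(path: str | Path) -> list[DiseaseAssociation]:
    path = Path(path)
    out: list[DiseaseAssociation] = []
    for lineno, row in _read_table(path, ["gene_id", "disease_id"]):
        mode = row.get("inheritance_mode", "").strip()
        if mode and mode not in INHERITANCE_MODES:
            raise InputFormatError(
                f"{path}, line {lineno}: invalid value '{mode}' in column 'inheritance_mode'"
            )
        genicity = row.get("genicity", "").strip()
        if genicity and genicity not in GENICITIES:
            raise InputFormatError(
                f"{path}, line {lineno}: invalid value '{genicity}' in column 'genicity'"
            )
        out.append(
            DiseaseAssociation(
                gene_id=_require(row["gene_id"], path, lineno, "gene_id"),
                disease_id=_require(row["disease_id"], path, lineno, "disease_id"),
                disease_class=row.get("disease_class", "").strip(),
                inheritance_mode=mode,
                genicity=genicity,
                mechanism_label=row.get("mechanism_label", "").strip(),
            )
        )
    return out


def read_housekeeping_list(path: str | Path) -> set[str]:
    """One gene id per line; comments and blank lines skipped."""
    out: set[str] = set()
    for _, row in _rows(path):
        out.add(row[0].strip())
    return out


def read_edge_list(path: str | Path) -> EdgeList:
    """Read raw interaction pairs verbatim (no cleaning)."""
    path = Path(path)
    pairs: list[EdgePair] = []
    it = _rows(path)
    try:
        _, header = next(it)
    except StopIteration:
        return EdgeList([])
    if len(header) < 2:
        raise InputFormatError(f"{path}, line 1: expected at least 2 columns")
    for lineno, row in it:
        if len(row) < 2:
            raise InputFormatError(f"{path}, line {lineno}: expected at least 2 fields")
        src = row[2].strip() if len(row) > 2 else ""
        pairs.append(EdgePair(row[0].strip(), row[1].strip(), src))
    return EdgeList(pairs)


_GAF_ASPECTS = {"C": "cellular_component", "F": "molecular_function", "P": "biological_process"}


def read_annotations(path: str | Path, namespace: str, gaf: bool = False) -> AnnotationTable:
    """Read gene→term annotations, keeping only the requested namespace.

    The native dialect is a headered TSV (gene_id, namespace, term). With
    ``gaf=True`` a GAF 2.x file is accepted instead: column 2 is the gene id,
    column 5 the term, and the one-letter Aspect (column 9) maps onto the GO
    namespace names. An input containing none of the requested namespace is
    not an error — an empty table is returned with a logged warning.
    """
    path = Path(path)
    table = AnnotationTable(namespace=namespace)
    seen_namespaces: set[str] = set()
    if gaf:
        for lineno, row in _rows(path):
            if len(row) < 9:
                raise InputFormatError(f"{path}, line {lineno}: GAF row has {len(row)} columns, expected >= 9")
            ns = _GAF_ASPECTS.get(row[8].strip(), row[8].strip())
            seen_namespaces.add(ns)
            if ns == namespace:
                table.add(row[1].strip(), row[4].strip())
    else:
        for lineno, row in _read_table(path, ["gene_id", "namespace", "term"]):
            ns = row["namespace"].strip()
            seen_namespaces.add(ns)
            if ns == namespace:
                table.add(
                    _require(row["gene_id"], path, lineno, "gene_id"),
                    _require(row["term"], path, lineno, "term"),
                )
    if not table.entries:
        logger.warning(
            "no annotations in namespace '%s' found in %s (namespaces present: %s)",
            namespace,
            path,
            ", ".join(sorted(seen_namespaces)) or "none",
        )
    return table


def read_text_records(path: str | Path) -> list[TextRecord]:
    path = Path(path)
    out: list[TextRecord] = []
    seen: set[str] = set()
    for lineno, row in _read_table(path, ["record_id", "gene_id", "text"]):
        rid = _require(row["record_id"], path, lineno, "record_id")
        if rid in seen:
            raise InputFormatError(f"{path}, line {lineno}: duplicate record_id '{rid}'")
        seen.add(rid)
        label = row.get("label", "").strip() or None
        if label is not None and label not in MECHANISM_LABELS:
            raise InputFormatError(f"{path}, line {lineno}: invalid value '{label}' in column 'label'")
        out.append(TextRecord(rid, row["gene_id"].strip(), row["text"], label))
    return out


# ---------------------------------------------------------------------------
# writers (canonical dialect; sorted, so equal contents give equal bytes)


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_orthology(path: str | Path, mapping: Mapping[str, str]) -> None:
    _write_tsv(path, ["human_gene_id", "mouse_gene_id"], sorted(mapping.items()))


def write_phenotypes(path: str | Path, phen: Mapping[str, Iterable[str]]) -> None:
    rows = sorted((mg, t) for mg, terms in phen.items() for t in terms)
    _write_tsv(path, ["mouse_gene_id", "phenotype_term"], rows)


def write_disease_associations(path: str | Path, assocs: Iterable[DiseaseAssociation]) -> None:
    rows = sorted(
        (a.gene_id, a.disease_id, a.disease_class, a.inheritance_mode, a.genicity, a.mechanism_label)
        for a in assocs
    )
    _write_tsv(
        path,
        ["gene_id", "disease_id", "disease_class", "inheritance_mode", "genicity", "mechanism_label"],
        rows,
    )


def write_housekeeping_list(path: str | Path, genes: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def write_edge_list(path: str | Path, edges: EdgeList) -> None:
    _write_tsv(path, ["protein_a", "protein_b", "source"], [(p.a, p.b, p.source) for p in edges])


def write_annotations(path: str | Path, *tables: AnnotationTable) -> None:
    """Write one or more namespaces into a single annotations file."""
    rows = sorted(
        (g, table.namespace, t) for table in tables for g, terms in table.entries.items() for t in terms
    )
    _write_tsv(path, ["gene_id", "namespace", "term"], rows)


def annotations_from_associations(assocs: Iterable[DiseaseAssociation]) -> AnnotationTable:
    """Flattened disease-class labels as an annotation namespace."""
    table = AnnotationTable(namespace="disease_class")
    for a in assocs:
        if a.disease_class:
            table.add(a.gene_id, a.disease_class)
    return table


def write_text_records(path: str | Path, records: Iterable[TextRecord]) -> None:
    rows = [(r.record_id, r.gene_id, r.known_label or "", r.text) for r in records]
    _write_tsv(path, ["record_id", "gene_id", "label", "text"], rows)
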