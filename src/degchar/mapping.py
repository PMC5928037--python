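"""Gene-list merging and gene-to-protein mapping.

The analysis starts from two differential-expression gene lists (one per
expression platform).  This module merges them into a unique gene set,
resolves genes to protein accessions through a mapping table, removes
duplicate proteins and annotated fragments, and partitions the resulting
protein set by regulation direction (up / down).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import InputError

SOURCES = ("rnaseq", "microarray")
DIRECTIONS = ("up", "down")
REGULATIONS = ("up", "down", "background")


@dataclass(frozen=True)
class GeneEntry:
    """One gene on a differential-expression list."""

    gene_id: str
    source: str  # rnaseq | microarray
    direction: str  # up | down

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if self.source not in SOURCES:
            raise InputError(f"unknown source {self.source!r}")
        if self.direction not in DIRECTIONS:
            raise InputError(f"unknown direction {self.direction!r}")


@dataclass
class ProteinRecord:
    """A protein with its encoding gene and regulation label."""

    accession: str
    gene_id: str
    sequence: str
    regulation: str = "background"  # up | down | background

    def __post_init__(self) -> None:
        if self.regulation not in REGULATIONS:
            raise InputError(f"unknown regulation {self.regulation!r}")
        if len(self.sequence) < 1:
            raise InputError(f"{self.accession}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MergeResult:
    genes: list[GeneEntry]
    conflicts: list[tuple[str, str, str]]  # gene_id, direction in A, direction in B


@dataclass
class MappingResult:
    proteins: list[ProteinRecord]
    unmapped: list[str]
    fragments_removed: list[str] = field(default_factory=list)


def merge_gene_lists(
    list_a: Sequence[GeneEntry], list_b: Sequence[GeneEntry]
) -> MergeResult:
    """Union the two gene lists by gene id.

    A gene present in both lists with conflicting directions is excluded and
    reported in the conflict list rather than silently resolved.  Within-list
    duplicates are an input error.
    """
    if not list_a or not list_b:
        raise InputError("gene lists must be non-empty")
    for name, lst in (("list A", list_a), ("list B", list_b)):
        ids = [g.gene_id for g in lst]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate gene ids within {name}: {dup}")

    merged: dict[str, GeneEntry] = {g.gene_id: g for g in list_a}
    conflicts: list[tuple[str, str, str]] = []
    for g in list_b:
        prev = merged.get(g.gene_id)
        if prev is None:
            merged[g.gene_id] = g
        elif prev.direction != g.direction:
            conflicts.append((g.gene_id, prev.direction, g.direction))
    for gene_id, _, _ in conflicts:
        merged.pop(gene_id, None)
    return MergeResult(genes=list(merged.values()), conflicts=conflicts)


def map_to_proteins(
    genes: Iterable[GeneEntry],
    mapping_table: Sequence[tuple[str, str, bool]],
    sequences: Mapping[str, str],
) -> MappingResult:
    """Resolve genes to deduplicated, fragment-free protein records.

    ``mapping_table`` rows are ``(gene_id, accession, is_fragment)``; a gene
    may map to several accessions (isoforms) and several genes may share an
    accession (deduplicated, first gene wins).  Genes absent from the table
    go to the unmapped report.  An accession in the table without a sequence
    is an input error.
    """
    by_gene: dict[str, list[tuple[str, bool]]] = {}
    for gene_id, accession, is_fragment in mapping_table:
        by_gene.setdefault(gene_id, []).append((accession, bool(is_fragment)))

    proteins: dict[str, ProteinRecord] = {}
    unmapped: list[str] = []
    fragments: list[str] = []
    for gene in genes:
        hits = by_gene.get(gene.gene_id)
        if not hits:
            unmapped.append(gene.gene_id)
            continue
        for accession, is_fragment in hits:
            if is_fragment:
                fragments.append(accession)
                continue
            if accession in proteins:
                continue  # duplicate protein across genes
            seq = sequences.get(accession)
            if seq is None:
                raise InputError(
                    f"accession {accession} (gene {gene.gene_id}) has no sequence"
                )
            proteins[accession] = ProteinRecord(
                accession=accession,
                gene_id=gene.gene_id,
                sequence=seq,
                regulation=gene.direction,
            )
    return MappingResult(
        proteins=list(proteins.values()),
        unmapped=unmapped,
        fragments_removed=fragments,
    )


def split_by_regulation(
    proteins: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (upregulated, downregulated)."""
    for p in proteins:
        if p.regulation == "background":
            raise InputError(f"{p.accession}: background record in regulation split")
    ups = [p for p in proteins if p.regulation == "up"]
    downs = [p for p in proteins if p.regulation == "down"]
    return ups, downs


# ---------------------------------------------------------------------------
# file I/O (TSV dialects shared with the synthetic generator)
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[GeneEntry]:
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                GeneEntry(row["gene_id"], row["source"], row["direction"])
            )
    return entries


def write_gene_list(path: str | Path, entries: Sequence[GeneEntry]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "source", "direction"])
        for g in entries:
            w.writerow([g.gene_id, g.source, g.direction])


def read_mapping_table(path: str | Path) -> list[tuple[str, str, bool]]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                (row["gene_id"], row["accession"], row.get("is_fragment", "0") == "1")
            )
    return rows


def write_mapping_table(
    path: str | Path, rows: Sequence[tuple[str, str, bool]]
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "accession", "is_fragment"])
        for gene_id, accession, frag in rows:
            w.writerow([gene_id, accession, int(frag)])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_table(path: str | Path, proteins: Sequence[ProteinRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "gene_id", "length", "regulation"])
        for p in proteins:
            w.writerow([p.accession, p.gene_id, p.length, p.regulation])
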