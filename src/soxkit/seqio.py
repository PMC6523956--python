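"""Readers/writers for the formats the pipeline touches, plus the
rank-indexed genome model shared by all downstream modules.

Coordinates are 1-based inclusive (GFF3 convention).  All gene-order
logic downstream (tandem/proximal windows, flank windows) works on
*ranks*: the 0-based index of a gene along its chromosome ordered by
ascending start coordinate, ties broken lexicographically by gene id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "ProteinRecord",
    "CdsRecord",
    "PrimerRecord",
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "read_protein_fasta",
    "read_cds_fasta",
    "write_protein_fasta",
    "write_cds_fasta",
    "read_primer_table",
    "translate_cds",
    "validate_cds_protein",
    "rank_index",
]


class Gff3ParseError(ValueError):
    """Malformed GFF3 input; message carries the 1-based line number."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene and its position in the gene order."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    rank: int = -1  # 0-based index along the chromosome, by start

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"CDS {self.gene_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerRecord:
    """A qPCR primer row: name, 5'-3' sequence and the declared length."""

    name: str
    sequence: str
    declared_length: int

    @property
    def computed_length(self) -> int:
        return len(self.sequence)

    @property
    def is_valid(self) -> bool:
        return self.computed_length == self.declared_length


# ---------------------------------------------------------------------------
# GFF3


def _assign_ranks(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Return genes with dense 0-based per-chromosome ranks.

    Ordering is by ascending start; ties broken lexicographically by
    gene_id so the ranking is deterministic.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    ranked: list[GeneModel] = []
    for chrom in by_chrom:
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(ordered):
            ranked.append(replace(g, rank=i))
    # preserve input order of the original list
    rank_of = {g.gene_id: g for g in ranked}
    return [rank_of[g.gene_id] for g in genes]


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene features from a GFF3 file into ranked :class:`GeneModel`\\ s.

    Only features of type ``gene`` are kept (the analysis is gene level;
    mRNA/exon children are ignored).  Ranks are computed per chromosome.

    Raises
    ------
    Gff3ParseError
        On a malformed line (with its line number) or a duplicate gene id.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise Gff3ParseError(f"line {lineno}: bad coordinates") from exc
            if strand not in {"+", "-"}:
                raise Gff3ParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise Gff3ParseError(f"line {lineno}: gene feature without ID")
            if gene_id in seen:
                raise Gff3ParseError(f"line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
            except ValueError as exc:
                raise Gff3ParseError(f"line {lineno}: {exc}") from exc
    return _assign_ranks(genes)


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene features as GFF3 (one line per gene, soxkit as source)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsoxkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def rank_index(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Map gene_id -> GeneModel for quick rank lookups."""
    return {g.gene_id: g for g in genes}


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(path: str | Path):
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r}: empty sequence")
        yield rec


def _gene_of(rec) -> str:
    # header token 'gene=<id>' links a protein to its gene; otherwise the
    # record id doubles as the gene id (one protein per gene)
    for token in rec.description.split()[1:]:
        if token.startswith("gene="):
            return token[5:]
    return rec.id


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins; a ``gene=`` token in the description links the gene."""
    return [
        ProteinRecord(rec.id, _gene_of(rec), str(rec.seq).upper())
        for rec in _iter_fasta(path)
    ]


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    return [CdsRecord(rec.id, str(rec.seq).upper()) for rec in _iter_fasta(path)]


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=f"gene={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# CDS / protein consistency

_STOPS = {"TAA", "TAG", "TGA"}


def translate_cds(cds: CdsRecord) -> str:
    """Translate a CDS with the standard code.

    A single terminal stop codon is trimmed before the divisibility and
    translation checks; an internal stop is an error.
    """
    seq = cds.sequence
    if len(seq) >= 3 and seq[-3:] in _STOPS:
        seq = seq[:-3]
    if len(seq) % 3 != 0:
        raise ValueError(
            f"CDS {cds.gene_id}: length {len(seq)} not divisible by 3 "
            "after terminal-stop trimming"
        )
    prot = str(Seq(seq).translate())
    if "*" in prot:
        raise ValueError(f"CDS {cds.gene_id}: internal stop codon")
    return prot


def validate_cds_protein(
    cds_records: Iterable[CdsRecord], proteins: Iterable[ProteinRecord]
) -> None:
    """Check translate(CDS) == protein for every linked pair."""
    prot_by_gene = {p.gene_id: p for p in proteins}
    for c in cds_records:
        p = prot_by_gene.get(c.gene_id)
        if p is None:
            continue
        translated = translate_cds(c)
        if translated != p.sequence:
            raise ValueError(
                f"gene {c.gene_id}: CDS translation does not match protein"
            )


# ---------------------------------------------------------------------------
# Primer tables

_DNA = set("ACGT")


def read_primer_table(path: str | Path | io.StringIO) -> list[PrimerRecord]:
    """Read a primer TSV with name, sequence and declared length columns.

    Rows whose sequence length differs from the declared length are kept
    but flagged via :attr:`PrimerRecord.is_valid`.  A non-ACGT character
    in a sequence is an error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("primer table needs name, sequence and length columns")
    name_col, seq_col, len_col = df.columns[:3]
    primers: list[PrimerRecord] = []
    for _, row in df.iterrows():
        name = str(row[name_col]).strip()
        seq = str(row[seq_col]).strip().upper()
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"primer {name!r}: non-ACGT character(s) {sorted(bad)}"
            )
        primers.append(PrimerRecord(name, seq, int(row[len_col])))
    return primers
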