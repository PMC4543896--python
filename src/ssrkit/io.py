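"""Readers and writers for the on-disk formats used throughout the toolkit.

All coordinates emitted by this package are 1-based and inclusive on both
ends (GFF3 convention), so the length of an interval is always
``end - start + 1``.  Sequences are uppercased on read; ambiguity codes are
preserved but treated as hard breaks by the repeat miner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty identifier")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class GeneModel:
    """A protein-coding gene with its structural parts.

    ``intron_parts`` is derived as the gaps between sorted exons.  When a
    gene has several transcripts the exon set is the union over all mRNAs
    and CDS/UTR parts come from the transcript with the longest total CDS.
    """

    gene_id: str
    span: GenomicInterval
    exon_parts: list[GenomicInterval] = field(default_factory=list)
    cds_parts: list[GenomicInterval] = field(default_factory=list)
    utr5_parts: list[GenomicInterval] = field(default_factory=list)
    utr3_parts: list[GenomicInterval] = field(default_factory=list)
    intron_parts: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass(frozen=True)
class AlignmentHit:
    """One line of 12-column tabular alignment output (outfmt-6 dialect).

    ``s_start`` may exceed ``s_end`` for a minus-strand hit; query
    coordinates are always ascending.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if self.q_start > self.q_end:
            raise ValueError("query coordinates must be ascending")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, uppercasing sequences.

    Raises :class:`FormatError` for an empty file or a file whose first
    non-blank line is not a FASTA header.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header, "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> Path:
    """Write records as wrapped FASTA; returns the path written."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")
    return path


_GFF_UTR5 = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_GFF_UTR3 = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def _feature_interval(feat) -> GenomicInterval:
    strand = feat.strand if feat.strand in ("+", "-") else "."
    return GenomicInterval(feat.seqid, feat.start, feat.end, strand)


def _merge_intervals(parts: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals on one sequence."""
    if not parts:
        return []
    parts = sorted(parts, key=lambda p: (p.start, p.end))
    merged = [parts[0]]
    for p in parts[1:]:
        last = merged[-1]
        if p.start <= last.end + 1:
            if p.end > last.end:
                merged[-1] = GenomicInterval(last.seq_id, last.start, p.end,
                                             last.strand)
        else:
            merged.append(p)
    return merged


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3.

    One :class:`GeneModel` per ``gene`` feature.  Exons are the union
    across all mRNAs; CDS and UTR parts are taken from the transcript with
    the longest total CDS; introns are the gaps between merged exons.
    A child feature extending outside its gene span raises ValueError.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        span = _feature_interval(gene)
        gene_id = gene.id
        exon_parts: list[GenomicInterval] = []
        best_cds: list[GenomicInterval] = []
        best_utr5: list[GenomicInterval] = []
        best_utr3: list[GenomicInterval] = []
        best_cds_len = -1
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        transcripts = mrnas if mrnas else [gene]
        for tx in transcripts:
            cds, utr5, utr3 = [], [], []
            for feat in db.children(tx, order_by="start"):
                ftype = feat.featuretype
                if ftype not in ({"exon", "CDS"} | _GFF_UTR5 | _GFF_UTR3):
                    continue
                iv = _feature_interval(feat)
                if iv.start < span.start or iv.end > span.end:
                    raise ValueError(
                        f"{path}: {ftype} {iv.start}-{iv.end} outside gene "
                        f"{gene_id} span {span.start}-{span.end}"
                    )
                if ftype == "exon":
                    exon_parts.append(iv)
                elif ftype == "CDS":
                    cds.append(iv)
                elif ftype in _GFF_UTR5:
                    utr5.append(iv)
                else:
                    utr3.append(iv)
            cds_len = sum(iv.length for iv in cds)
            if cds_len > best_cds_len:
                best_cds_len = cds_len
                best_cds, best_utr5, best_utr3 = cds, utr5, utr3
        exon_union = _merge_intervals(exon_parts)
        if not exon_union:
            # annotation without explicit exon rows: exons = CDS + UTRs
            exon_union = _merge_intervals(best_cds + best_utr5 + best_utr3)
        introns = [
            GenomicInterval(span.seq_id, a.end + 1, b.start - 1, span.strand)
            for a, b in zip(exon_union, exon_union[1:])
            if b.start > a.end + 1
        ]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                span=span,
                exon_parts=exon_union,
                cds_parts=sorted(best_cds),
                utr5_parts=sorted(best_utr5),
                utr3_parts=sorted(best_utr3),
                intron_parts=introns,
            )
        )
    return genes


def read_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tab-separated alignment hits (BLAST outfmt 6).

    Empty files yield an empty list; a line with a column count other
    than 12 raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, "
                    f"got {len(cols)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    align_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tsv_catalog(records: Sequence[dict], columns: Sequence[str],
                      path: str | Path) -> Path:
    """Write homogeneous records as a TSV catalog with a fixed column order.

    Missing keys are written as empty cells; the file always contains a
    header row even for zero records.
    """
    path = Path(path)
    with open(path, "w", newline="") as out:
        writer = csv.DictWriter(
            out, fieldnames=list(columns), delimiter="\t",
            restval="", extrasaction="ignore", lineterminator="\n",
        )
        writer.writeheader()
        for rec in records:
            writer.writerow(rec)
    return path


def read_tsv_catalog(path: str | Path) -> list[dict]:
    """Read a TSV catalog back into a list of string-valued dicts."""
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))
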