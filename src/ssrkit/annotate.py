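"""Assign SSR loci to genomic contexts and tabulate per-context breakdowns.

Each locus gets exactly one primary context - CDS, 5'-UTR, 3'-UTR,
intron, upstream (1000 bp 5' of the gene) or intergenic - decided by the
feature overlapping the tract midpoint, with genic contexts taking
precedence over upstream and upstream over intergenic.  "Exon" is a
derived super-category: CDS plus UTR portions (plus exonic sequence whose
UTR status is unknown when the annotation lacks UTR features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io import GeneModel, GenomicInterval
from .miner import MOTIF_SIZE_NAMES, SSRLocus

logger = logging.getLogger(__name__)

CONTEXT_CDS = "CDS"
CONTEXT_UTR5 = "UTR5"
CONTEXT_UTR3 = "UTR3"
CONTEXT_UTR_UNKNOWN = "UTR_unknown"  # exonic, non-CDS, no UTR annotation
CONTEXT_INTRON = "intron"
CONTEXT_UPSTREAM = "upstream"
CONTEXT_INTERGENIC = "intergenic"

#: Primary contexts in precedence order (highest first).
CONTEXT_PRECEDENCE = [
    CONTEXT_CDS, CONTEXT_UTR5, CONTEXT_UTR3, CONTEXT_UTR_UNKNOWN,
    CONTEXT_INTRON, CONTEXT_UPSTREAM, CONTEXT_INTERGENIC,
]

EXONIC_CONTEXTS = {CONTEXT_CDS, CONTEXT_UTR5, CONTEXT_UTR3,
                   CONTEXT_UTR_UNKNOWN}


@dataclass(frozen=True)
class GenomicContext:
    """Primary context of one SSR locus, with the owning gene if genic."""

    primary: str
    gene_id: str | None = None

    @property
    def exon(self) -> bool:
        return self.primary in EXONIC_CONTEXTS


class FeatureIndex:
    """Interval index over gene parts for fast midpoint queries."""

    def __init__(self, genes: list[GeneModel], upstream_len: int = 1000,
                 seq_lengths: dict[str, int] | None = None) -> None:
        if upstream_len <= 0:
            raise ValueError("upstream_len must be positive")
        self.upstream_len = upstream_len
        self._trees: dict[str, IntervalTree] = {}
        seq_lengths = seq_lengths or {}
        for gene in genes:
            try:
                self._add_gene(gene, seq_lengths)
            except ValueError as exc:
                logger.warning("skipping malformed gene %s: %s",
                               gene.gene_id, exc)

    def _tree(self, seq_id: str) -> IntervalTree:
        return self._trees.setdefault(seq_id, IntervalTree())

    def _add(self, iv: GenomicInterval, label: str, gene: GeneModel) -> None:
        # intervaltree is half-open; store [start, end+1)
        self._tree(iv.seq_id).addi(iv.start, iv.end + 1,
                                   (label, gene.gene_id, gene.span.start))

    def _add_gene(self, gene: GeneModel,
                  seq_lengths: dict[str, int]) -> None:
        span = gene.span
        cds_cover = set()
        for iv in gene.cds_parts:
            self._add(iv, CONTEXT_CDS, gene)
            cds_cover.add((iv.start, iv.end))
        for iv in gene.utr5_parts:
            self._add(iv, CONTEXT_UTR5, gene)
        for iv in gene.utr3_parts:
            self._add(iv, CONTEXT_UTR3, gene)
        for iv in gene.intron_parts:
            self._add(iv, CONTEXT_INTRON, gene)
        # exon minus known CDS/UTR cover -> UTR-unknown fallback regions
        has_utr = bool(gene.utr5_parts or gene.utr3_parts)
        for exon in gene.exon_parts:
            if has_utr:
                continue
            pieces = [(exon.start, exon.end)]
            for cds in gene.cds_parts:
                pieces = _subtract(pieces, (cds.start, cds.end))
            for a, b in pieces:
                self._add(GenomicInterval(exon.seq_id, a, b, exon.strand),
                          CONTEXT_UTR_UNKNOWN, gene)
        # strand-aware upstream window, clamped to the sequence
        if span.strand == "-":
            up_start, up_end = span.end + 1, span.end + self.upstream_len
            limit = seq_lengths.get(span.seq_id)
            if limit is not None:
                up_end = min(up_end, limit)
        else:
            up_start, up_end = span.start - self.upstream_len, span.start - 1
            up_start = max(up_start, 1)
        if up_start <= up_end:
            self._add(GenomicInterval(span.seq_id, up_start, up_end,
                                      span.strand), CONTEXT_UPSTREAM, gene)

    def query_point(self, seq_id: str, pos: int) -> list[tuple[str, str, int]]:
        tree = self._trees.get(seq_id)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]


def _subtract(pieces: list[tuple[int, int]],
              cut: tuple[int, int]) -> list[tuple[int, int]]:
    out = []
    for a, b in pieces:
        if cut[1] < a or cut[0] > b:
            out.append((a, b))
            continue
        if a < cut[0]:
            out.append((a, cut[0] - 1))
        if b > cut[1]:
            out.append((cut[1] + 1, b))
    return out


def build_feature_index(genes: list[GeneModel], upstream_len: int = 1000,
                        seq_lengths: dict[str, int] | None = None
                        ) -> FeatureIndex:
    """Build the queryable feature index used by :func:`annotate_locus`."""
    return FeatureIndex(genes, upstream_len=upstream_len,
                        seq_lengths=seq_lengths)


def annotate_locus(locus: SSRLocus, index: FeatureIndex,
                   seq_lengths: dict[str, int] | None = None
                   ) -> GenomicContext:
    """Context of the feature containing the SSR tract midpoint.

    Ties across feature types are broken by the precedence
    CDS > UTR5 > UTR3 > intron > upstream; ties between genes at equal
    precedence go to the gene earliest in coordinate order.
    """
    iv = locus.interval
    if seq_lengths is not None:
        limit = seq_lengths.get(iv.seq_id)
        if limit is not None and iv.end > limit:
            raise ValueError(
                f"locus {locus.locus_id} extends beyond sequence end {limit}"
            )
    midpoint = (iv.start + iv.end) // 2
    hits = index.query_point(iv.seq_id, midpoint)
    if not hits:
        return GenomicContext(CONTEXT_INTERGENIC)
    rank = {label: i for i, label in enumerate(CONTEXT_PRECEDENCE)}
    label, gene_id, _ = min(hits, key=lambda h: (rank[h[0]], h[2], h[1]))
    competing = {g for lab, g, _ in hits if lab == label}
    if len(competing) > 1:
        logger.warning("locus %s claimed by genes %s; keeping %s",
                       locus.locus_id, sorted(competing), gene_id)
    return GenomicContext(label, gene_id=gene_id)


@dataclass
class ContextBreakdown:
    """Counts of SSRs per context and per motif size within context."""

    counts: dict[str, int]
    counts_by_size: dict[str, dict[int, int]]
    exon_count: int
    total: int


def context_breakdown(
    annotated: list[tuple[SSRLocus, GenomicContext]]
) -> ContextBreakdown:
    """Tabulate per-context counts; ``exon_count`` is the CDS+UTR union."""
    counts = {c: 0 for c in CONTEXT_PRECEDENCE}
    by_size = {c: {k: 0 for k in MOTIF_SIZE_NAMES} for c in CONTEXT_PRECEDENCE}
    exon_count = 0
    for locus, ctx in annotated:
        counts[ctx.primary] += 1
        by_size[ctx.primary][locus.motif_size] += 1
        if ctx.exon:
            exon_count += 1
    return ContextBreakdown(
        counts=counts,
        counts_by_size=by_size,
        exon_count=exon_count,
        total=len(annotated),
    )
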