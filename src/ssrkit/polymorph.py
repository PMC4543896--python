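"""Call polymorphic SSRs at anchored loci and export marker products.

Under the perfect-repeat model a locus is polymorphic when the number of
whole repeat units differs between the two genomes, so the bp difference
is always a multiple of the motif length.  Differences are binned 2..20
plus an open ">20" bin; a validation subset uses a >= 4 bp cut-off.
Primer-design targets are exported as Boulder-IO records (genome A
template, unmasked) for external Primer3 runs - no primer picking is
done here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .anchor import AnchoredPair, DEFAULT_FLANK_LEN
from .annotate import GenomicContext
from .io import SequenceRecord, write_tsv_catalog

logger = logging.getLogger(__name__)

DEFAULT_MIN_DIFF_BP = 2
VALIDATION_MIN_DIFF_BP = 4
BIN_LABELS = [str(d) for d in range(2, 21)] + [">20"]


@dataclass(frozen=True)
class PolymorphicCall:
    """Repeat-length comparison at one anchored locus pair."""

    pair: AnchoredPair
    diff_units: int
    diff_bp: int
    diff_bin: str | None
    direction: str  # expansion_in_b / contraction_in_b / equal
    polymorphic: bool
    context: GenomicContext | None = None

    @property
    def marker_id(self) -> str:
        return f"SSR_{self.pair.locus_a.locus_id}"


@dataclass(frozen=True)
class RejectedLocus:
    """Anchored pair excluded from calling, with the reason."""

    pair: AnchoredPair
    reason: str


def diff_bin_label(diff_bp: int) -> str:
    return ">20" if diff_bp > 20 else str(diff_bp)


def call_polymorphic(pair: AnchoredPair,
                     min_diff_bp: int = DEFAULT_MIN_DIFF_BP,
                     context: GenomicContext | None = None
                     ) -> PolymorphicCall | RejectedLocus:
    """Compare repeat counts at an anchored pair.

    Pairs whose loci belong to different canonical motif families are
    returned as :class:`RejectedLocus` records rather than raised.
    """
    a, b = pair.locus_a, pair.locus_b
    if a.canonical_family != b.canonical_family:
        logger.warning("rejecting pair %s / %s: motif families differ "
                       "(%s vs %s)", a.locus_id, b.locus_id,
                       a.canonical_family, b.canonical_family)
        return RejectedLocus(pair, reason="motif_family_mismatch")
    diff_units = abs(a.repeat_count - b.repeat_count)
    diff_bp = diff_units * a.motif_size
    if b.repeat_count > a.repeat_count:
        direction = "expansion_in_b"
    elif b.repeat_count < a.repeat_count:
        direction = "contraction_in_b"
    else:
        direction = "equal"
    polymorphic = diff_bp >= min_diff_bp and diff_units > 0
    return PolymorphicCall(
        pair=pair,
        diff_units=diff_units,
        diff_bp=diff_bp,
        diff_bin=diff_bin_label(diff_bp) if polymorphic else None,
        direction=direction,
        polymorphic=polymorphic,
        context=context,
    )


def call_all(pairs: list[AnchoredPair],
             min_diff_bp: int = DEFAULT_MIN_DIFF_BP,
             contexts: dict[str, GenomicContext] | None = None
             ) -> tuple[list[PolymorphicCall], list[RejectedLocus]]:
    """Call every anchored pair; contexts are looked up by genome A locus."""
    calls: list[PolymorphicCall] = []
    rejected: list[RejectedLocus] = []
    for pair in pairs:
        ctx = (contexts or {}).get(pair.locus_a.locus_id)
        result = call_polymorphic(pair, min_diff_bp, context=ctx)
        if isinstance(result, RejectedLocus):
            rejected.append(result)
        else:
            calls.append(result)
    return calls, rejected


def bin_differences(calls: list[PolymorphicCall]) -> dict[str, int]:
    """Histogram of bp differences over bins 2..20 and ">20".

    All calls must be polymorphic.  The returned dict preserves bin
    order; use :func:`is_declining` for the frequency-vs-length trend.
    """
    hist = {label: 0 for label in BIN_LABELS}
    for call in calls:
        if not call.polymorphic:
            raise ValueError("bin_differences expects polymorphic calls only")
        hist[call.diff_bin] += 1
    return hist


def is_declining(hist: dict[str, int]) -> bool:
    """True when occupied bins show non-increasing counts with length."""
    occupied = [hist[label] for label in BIN_LABELS if hist[label] > 0]
    return all(a >= b for a, b in zip(occupied, occupied[1:]))


def select_validation_set(calls: list[PolymorphicCall],
                          min_diff_bp: int = VALIDATION_MIN_DIFF_BP
                          ) -> list[PolymorphicCall]:
    """Subset with diff >= ``min_diff_bp``, ordered by genome A position."""
    subset = [c for c in calls if c.polymorphic and c.diff_bp >= min_diff_bp]
    subset.sort(key=lambda c: (c.pair.locus_a.interval.seq_id,
                               c.pair.locus_a.interval.start))
    return subset


def export_primer_targets(calls: list[PolymorphicCall],
                          genome_a: dict[str, SequenceRecord],
                          path,
                          flank_len: int = DEFAULT_FLANK_LEN) -> int:
    """Write Boulder-IO records for external Primer3 primer design.

    Each record carries the unmasked genome A window as
    SEQUENCE_TEMPLATE and the tract as SEQUENCE_TARGET "<start>,<length>"
    in 1-based coordinates (PRIMER_FIRST_BASE_INDEX=1 is emitted so
    Primer3 interprets them the same way).  Returns the number of records
    written; templates too short to design against are skipped with a
    warning.
    """
    n_written = 0
    with open(path, "w") as out:
        for call in calls:
            locus = call.pair.locus_a
            iv = locus.interval
            rec = genome_a.get(iv.seq_id)
            if rec is None:
                logger.warning("skipping %s: sequence %s absent",
                               call.marker_id, iv.seq_id)
                continue
            left_start = max(1, iv.start - flank_len)
            right_end = min(len(rec.seq), iv.end + flank_len)
            template = rec.seq[left_start - 1 : right_end]
            if len(template) < iv.length + 40:
                logger.warning("skipping %s: template of %d bp leaves "
                               "< 40 bp of flank", call.marker_id,
                               len(template))
                continue
            target_start = iv.start - left_start + 1  # 1-based in template
            out.write(f"SEQUENCE_ID={call.marker_id}\n")
            out.write(f"SEQUENCE_TEMPLATE={template}\n")
            out.write(f"SEQUENCE_TARGET={target_start},{iv.length}\n")
            out.write("PRIMER_FIRST_BASE_INDEX=1\n")
            out.write("=\n")
            n_written += 1
    return n_written


def read_boulder(path) -> list[dict[str, str]]:
    """Parse Boulder-IO records (KEY=VALUE lines, '=' separator)."""
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line == "=":
                if current:
                    records.append(current)
                current = {}
            elif line:
                key, _, value = line.partition("=")
                current[key] = value
    if current:
        records.append(current)
    return records


CATALOG_COLUMNS = [
    "marker_id", "seq_id_a", "start_a", "end_a", "seq_id_b", "start_b",
    "end_b", "motif", "canonical_family", "class", "repeat_count_a",
    "repeat_count_b", "diff_bp", "diff_bin", "context", "gene_id",
]


def export_catalog(calls: list[PolymorphicCall], path) -> int:
    """Write the polymorphic-marker catalog TSV; returns rows written."""
    rows = []
    for call in calls:
        a, b = call.pair.locus_a, call.pair.locus_b
        ctx = call.context
        rows.append({
            "marker_id": call.marker_id,
            "seq_id_a": a.interval.seq_id,
            "start_a": a.interval.start,
            "end_a": a.interval.end,
            "seq_id_b": b.interval.seq_id,
            "start_b": b.interval.start,
            "end_b": b.interval.end,
            "motif": a.motif,
            "canonical_family": a.canonical_family,
            "class": a.ssr_class,
            "repeat_count_a": a.repeat_count,
            "repeat_count_b": b.repeat_count,
            "diff_bp": call.diff_bp,
            "diff_bin": call.diff_bin or "",
            "context": ctx.primary if ctx else "",
            "gene_id": (ctx.gene_id or "") if ctx else "",
        })
    write_tsv_catalog(rows, CATALOG_COLUMNS, path)
    return len(rows)
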