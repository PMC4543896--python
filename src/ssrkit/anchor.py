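"""Pair orthologous SSR loci between two assemblies via flanking sequence.

For every SSR a query window is built from up to 250 bp of flank on each
side with the repeat tract itself hard-masked to N, so that the quantity
being compared downstream (tract length) cannot influence matching.
Windows from genome A are aligned against genome B and vice versa; a
locus pair is anchored only when each window's passing hits all land on
the other locus's window, in both directions (reciprocal unique hit,
E-value <= 1e-40 by default).

The built-in aligner is an ungapped seed-and-extend matcher for
desk-scale and simulated data.  Its E-value is a surrogate computed as
``E = m * n * 2**(-S)`` with score ``S = 2*matches - 3*mismatches``; for
genome-scale work, import external BLASTN tabular hits instead via
:func:`ssrkit.io.read_alignment_table` - the reciprocal filter accepts
either source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import AlignmentHit, SequenceRecord
from .miner import SSRLocus, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 250
DEFAULT_EVALUE_MAX = 1e-40
SEED_LEN = 50
#: hit-to-window assignment: subject overlap must cover >= this fraction
#: of the hit length
LANDING_MIN_OVERLAP = 0.5

# ungapped extension scoring (megablast-like)
MATCH_SCORE = 2
MISMATCH_SCORE = -3
XDROP = 12


@dataclass(frozen=True)
class AnchorQuery:
    """Flanking-sequence query window for one SSR locus."""

    query_id: str
    genome: str
    locus: SSRLocus
    window_seq: str
    window_start: int  # 1-based genomic start of the window
    mask_start: int    # 1-based offset of the masked tract within the window
    mask_end: int

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.window_seq) - 1


@dataclass(frozen=True)
class AnchoredPair:
    """A reciprocally-unique orthologous SSR locus pair."""

    locus_a: SSRLocus
    locus_b: SSRLocus
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit
    reciprocal: bool = True


def make_query_id(genome: str, locus: SSRLocus) -> str:
    return f"{genome}|{locus.locus_id}"


def extract_flanks(locus: SSRLocus, genome: dict[str, SequenceRecord],
                   flank_len: int = DEFAULT_FLANK_LEN,
                   genome_label: str = "A") -> AnchorQuery:
    """Build the anchor window: left flank + N-masked tract + right flank.

    Flanks truncated by a sequence end are kept at their true length.
    """
    iv = locus.interval
    rec = genome.get(iv.seq_id)
    if rec is None or iv.end > len(rec.seq):
        raise ValueError(f"locus {locus.locus_id} not found on genome "
                         f"{genome_label}")
    left_start = max(1, iv.start - flank_len)
    right_end = min(len(rec.seq), iv.end + flank_len)
    left = rec.seq[left_start - 1 : iv.start - 1]
    right = rec.seq[iv.end : right_end]
    window = left + "N" * iv.length + right
    return AnchorQuery(
        query_id=make_query_id(genome_label, locus),
        genome=genome_label,
        locus=locus,
        window_seq=window,
        window_start=left_start,
        mask_start=len(left) + 1,
        mask_end=len(left) + iv.length,
    )


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend_ungapped(q: str, s: str, qi: int, si: int,
                     seed: int) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension around an exact seed.

    Returns (q_start, q_end, s_start, s_end, n_mismatch), 0-based
    inclusive coordinates trimmed to the maximal-score extent.
    """
    # right extension
    score = best = seed * MATCH_SCORE
    qe_best, j = qi + seed - 1, qi + seed
    mm = mm_best_r = 0
    while j < len(q) and si + (j - qi) < len(s):
        cq, cs = q[j], s[si + (j - qi)]
        if cq == "N" or cs == "N":
            break
        if cq == cs:
            score += MATCH_SCORE
        else:
            score += MISMATCH_SCORE
            mm += 1
        if score > best:
            best, qe_best, mm_best_r = score, j, mm
        if best - score > XDROP:
            break
        j += 1
    # left extension
    score = best
    qs_best, j = qi, qi - 1
    mm = mm_best_l = 0
    while j >= 0 and si - (qi - j) >= 0:
        cq, cs = q[j], s[si - (qi - j)]
        if cq == "N" or cs == "N":
            break
        if cq == cs:
            score += MATCH_SCORE
        else:
            score += MISMATCH_SCORE
            mm += 1
        if score > best:
            best, qs_best, mm_best_l = score, j, mm
        if best - score > XDROP:
            break
        j -= 1
    qs, qe = qs_best, qe_best
    ss = si - (qi - qs)
    se = si + (qe - qi)
    return qs, qe, ss, se, mm_best_l + mm_best_r


def _surrogate_evalue(matches: int, mismatches: int, m: int, n: int) -> float:
    s = MATCH_SCORE * matches + MISMATCH_SCORE * mismatches
    if s > 4000:  # 2**-4000 underflows; the E-value is effectively zero
        return 0.0
    return m * n * 2.0 ** (-s)


def builtin_align(queries: list[AnchorQuery],
                  subject: dict[str, SequenceRecord],
                  seed_len: int = SEED_LEN) -> list[AlignmentHit]:
    """Ungapped seed-and-extend search of anchor windows against a genome.

    Both strands are searched; minus-strand hits are reported with
    ``s_start > s_end``.  All distinct maximal extensions are reported so
    that the reciprocal-uniqueness filter sees any ambiguity.
    """
    hits: list[AlignmentHit] = []
    indexes = {rec.id: _seed_index(rec.seq, seed_len)
               for rec in subject.values()}
    for query in queries:
        qseq = query.window_seq
        m = len(qseq)
        for strand, q in (("+", qseq), ("-", reverse_complement(qseq))):
            seen: set[tuple[str, str, int, int]] = set()
            covered: dict[tuple[str, str, int], int] = {}  # diagonal -> q_end
            for sid, index in indexes.items():
                sseq = subject[sid].seq
                n = len(sseq)
                for qi in range(0, m - seed_len + 1):
                    kmer = q[qi : qi + seed_len]
                    if "N" in kmer:
                        continue
                    for si in index.get(kmer, ()):
                        diag = (sid, strand, si - qi)
                        if covered.get(diag, -1) >= qi + seed_len - 1:
                            continue  # seed inside an already-found hit
                        qs, qe, ss, se, mm = _extend_ungapped(
                            q, sseq, qi, si, seed_len)
                        covered[diag] = max(covered.get(diag, -1), qe)
                        key = (sid, strand, ss - qs, se)  # diagonal + extent
                        if key in seen:
                            continue
                        seen.add(key)
                        length = qe - qs + 1
                        matches = length - mm
                        ev = _surrogate_evalue(matches, mm, m, n)
                        if strand == "+":
                            q_start, q_end = qs + 1, qe + 1
                            s_start, s_end = ss + 1, se + 1
                        else:
                            q_start, q_end = m - qe, m - qs
                            s_start, s_end = se + 1, ss + 1
                        hits.append(AlignmentHit(
                            query_id=query.query_id,
                            subject_id=sid,
                            percent_identity=round(100.0 * matches / length,
                                                   2),
                            align_length=length,
                            mismatches=mm,
                            gap_opens=0,
                            q_start=q_start,
                            q_end=q_end,
                            s_start=s_start,
                            s_end=s_end,
                            evalue=ev,
                            bit_score=float(
                                MATCH_SCORE * matches + MISMATCH_SCORE * mm),
                        ))
    return hits


def _landing_window(hit: AlignmentHit,
                    windows: list[AnchorQuery]) -> AnchorQuery | None:
    """Window the hit lands on: subject-side overlap >= 50% of hit length.

    If the subject id is itself a window id (windows aligned against the
    window FASTA rather than the genome), the assignment is direct.
    """
    by_id = {w.query_id: w for w in windows}
    if hit.subject_id in by_id:
        return by_id[hit.subject_id]
    lo, hi = min(hit.s_start, hit.s_end), max(hit.s_start, hit.s_end)
    length = hi - lo + 1
    best: AnchorQuery | None = None
    best_ov = 0
    for w in windows:
        if w.locus.interval.seq_id != hit.subject_id:
            continue
        ov = min(hi, w.window_end) - max(lo, w.window_start) + 1
        if ov > best_ov:
            best_ov, best = ov, w
    if best is not None and best_ov >= LANDING_MIN_OVERLAP * length:
        return best
    return None


def reciprocal_unique_pairs(
    hits_ab: list[AlignmentHit],
    hits_ba: list[AlignmentHit],
    queries_a: list[AnchorQuery],
    queries_b: list[AnchorQuery],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[AnchoredPair]:
    """Retain locus pairs with mutually unique passing hits.

    A query is *unambiguous* when every hit with E <= ``evalue_max``
    lands on one and the same window of the other genome (a passing hit
    landing nowhere, or on a second window, disqualifies the query).  A
    pair is emitted when A's unique target is B and B's unique target is
    A; the resulting mapping is one-to-one by construction.
    """
    ids_a = {q.query_id for q in queries_a}
    ids_b = {q.query_id for q in queries_b}
    for hit in hits_ab:
        if hit.query_id not in ids_a:
            raise ValueError(f"A->B hit references unknown query "
                             f"{hit.query_id!r}")
    for hit in hits_ba:
        if hit.query_id not in ids_b:
            raise ValueError(f"B->A hit references unknown query "
                             f"{hit.query_id!r}")

    AMBIGUOUS = "__ambiguous__"

    def unique_targets(hits, windows, evalue_max):
        state: dict[str, tuple[str, AlignmentHit] | str] = {}
        for hit in hits:
            if hit.evalue > evalue_max:
                continue
            cur = state.get(hit.query_id)
            if cur == AMBIGUOUS:
                continue
            landing = _landing_window(hit, windows)
            if landing is None:
                # a passing hit landing on no window is real ambiguity
                state[hit.query_id] = AMBIGUOUS
            elif cur is None:
                state[hit.query_id] = (landing.query_id, hit)
            elif cur[0] != landing.query_id:
                state[hit.query_id] = AMBIGUOUS
            elif hit.evalue < cur[1].evalue:
                state[hit.query_id] = (landing.query_id, hit)
        return {q: t for q, t in state.items() if t != AMBIGUOUS}

    fwd = unique_targets(hits_ab, queries_b, evalue_max)
    rev = unique_targets(hits_ba, queries_a, evalue_max)
    by_id_a = {q.query_id: q for q in queries_a}
    by_id_b = {q.query_id: q for q in queries_b}
    pairs: list[AnchoredPair] = []
    for qa_id in sorted(fwd):
        target_b, hit_ab = fwd[qa_id]
        back = rev.get(target_b)
        if back is None or back[0] != qa_id:
            continue
        pairs.append(AnchoredPair(
            locus_a=by_id_a[qa_id].locus,
            locus_b=by_id_b[target_b].locus,
            hit_ab=hit_ab,
            hit_ba=back[1],
            reciprocal=True,
        ))
    return pairs


def anchor_loci(
    ssrs_a: list[SSRLocus],
    genome_a: dict[str, SequenceRecord],
    ssrs_b: list[SSRLocus],
    genome_b: dict[str, SequenceRecord],
    flank_len: int = DEFAULT_FLANK_LEN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    hits_ab: list[AlignmentHit] | None = None,
    hits_ba: list[AlignmentHit] | None = None,
) -> list[AnchoredPair]:
    """End-to-end anchoring: windows, alignment (built-in unless external
    hit tables are supplied), reciprocal-unique filtering."""
    queries_a = [extract_flanks(s, genome_a, flank_len, "A") for s in ssrs_a]
    queries_b = [extract_flanks(s, genome_b, flank_len, "B") for s in ssrs_b]
    if hits_ab is None:
        hits_ab = builtin_align(queries_a, genome_b)
    if hits_ba is None:
        hits_ba = builtin_align(queries_b, genome_a)
    return reciprocal_unique_pairs(hits_ab, hits_ba, queries_a, queries_b,
                                   evalue_max)
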