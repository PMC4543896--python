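"""Perfect-microsatellite detection, classification and genome summaries.

Mining follows the MISA-style criteria used for the chickpea genome
comparison: a tract is reported when a 2-nt motif repeats at least 6
times, or a 3-6 nt motif at least 5 times; mononucleotide runs are
excluded.  Tracts of at least 20 bp are the hypervariable class I, tracts
of 12 to <20 bp the potentially variable class II.

Detection model
---------------
For each motif size ``k`` the sequence is decomposed into *character-
maximal* k-periodic regions: maximal stretches where ``s[j] == s[j+k]``
for every interior position, with any non-ACGT symbol breaking the
region.  Each region yields at most one tract: the leftmost run of whole
motif copies (partial trailing units are discarded, so tract length is
always a multiple of the motif size).  A motif that is itself a power of
a shorter unit (``ATAT``, ``AAA...``) is never reported - such regions
surface at their primitive period instead, which implements the
"prefer the smaller motif size" overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .io import GenomicInterval, SequenceRecord

MOTIF_SIZE_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

#: Minimum whole repeat units per motif size (MISA criteria).
DEFAULT_MIN_REPEATS = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Class I/II boundary in bp: class I is >= 20 bp, class II is [12, 20).
CLASS_I_MIN_BP = 20
CLASS_II_MIN_BP = 12


@dataclass(frozen=True)
class MiningParams:
    """Thresholds controlling perfect-SSR detection."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_gap: int = 100
    exclude_mononucleotide: bool = True

    def __post_init__(self) -> None:
        if not set(self.min_repeats) <= {2, 3, 4, 5, 6}:
            raise ValueError("min_repeats keys must be motif sizes 2..6")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite tract.

    ``motif`` is the repeat unit as observed on the forward strand;
    ``canonical_family`` normalises it across strand and phase.
    """

    interval: GenomicInterval
    motif: str
    canonical_family: str
    repeat_count: int
    ssr_class: str
    compound_id: str | None = None

    @property
    def motif_size(self) -> int:
        return len(self.motif)

    @property
    def tract_length_bp(self) -> int:
        return self.repeat_count * len(self.motif)

    @property
    def locus_id(self) -> str:
        iv = self.interval
        return f"{iv.seq_id}:{iv.start}-{iv.end}"


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_family(motif: str) -> str:
    """Canonical label for a motif's strand/phase equivalence class.

    Returns the lexicographically smallest string among all rotations of
    the motif and all rotations of its reverse complement, so that e.g.
    TA, AT and their complements all map to "AT".
    """
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains non-ACGT symbols: {motif!r}")
    rc = reverse_complement(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def classify_ssr(tract_length_bp: int) -> str:
    """Class I (>= 20 bp) or class II (12 to < 20 bp)."""
    if tract_length_bp < CLASS_II_MIN_BP:
        raise ValueError(
            f"tract of {tract_length_bp} bp is below the class II minimum "
            f"of {CLASS_II_MIN_BP} bp"
        )
    return "I" if tract_length_bp >= CLASS_I_MIN_BP else "II"


def find_perfect_ssrs(record: SequenceRecord,
                      params: MiningParams | None = None) -> list[SSRLocus]:
    """Detect all perfect SSR tracts in one sequence.

    Returns loci sorted by start position (ties by motif size).  Tracts
    never span a non-ACGT symbol and motifs are always primitive.
    """
    params = params or MiningParams()
    seq = record.seq
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C"))
        | (arr == ord("G")) | (arr == ord("T"))
    )
    for k, min_rep in sorted(params.min_repeats.items()):
        if n < k * min_rep:
            continue
        # eq[j] == True  <=>  s[j] == s[j+k] and both positions are ACGT
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        # run boundaries of consecutive True values
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(edges[::2], edges[1::2]):
            # region of k-periodic characters: [a, b-1+k] inclusive
            a, b = int(a), int(b)
            region_len = (b - a) + k
            repeat_count = region_len // k
            if repeat_count < min_rep:
                continue
            motif = seq[a : a + k]
            if not is_primitive(motif):
                continue
            tract_len = repeat_count * k
            interval = GenomicInterval(record.id, a + 1, a + tract_len)
            loci.append(
                SSRLocus(
                    interval=interval,
                    motif=motif,
                    canonical_family=canonical_family(motif),
                    repeat_count=repeat_count,
                    ssr_class=classify_ssr(tract_len),
                )
            )
    loci.sort(key=lambda s: (s.interval.start, s.motif_size))
    return loci


def merge_compound(ssrs: list[SSRLocus],
                   compound_max_gap: int = 100) -> list[SSRLocus]:
    """Group SSRs separated by at most ``compound_max_gap`` bp.

    Input must be sorted by start position on a single sequence; members
    of a group share a ``compound_id`` of the form ``<seq>:c<n>``,
    isolated loci keep ``compound_id=None``.
    """
    for prev, cur in zip(ssrs, ssrs[1:]):
        if cur.interval.seq_id == prev.interval.seq_id \
                and cur.interval.start < prev.interval.start:
            raise ValueError("SSR list must be sorted by start position")
    out: list[SSRLocus] = []
    group: list[SSRLocus] = []
    counter = 0

    def flush() -> int:
        nonlocal counter
        if len(group) >= 2:
            counter += 1
            cid = f"{group[0].interval.seq_id}:c{counter}"
            out.extend(replace(s, compound_id=cid) for s in group)
        else:
            out.extend(replace(s, compound_id=None) for s in group)
        group.clear()
        return counter

    for ssr in ssrs:
        if group:
            prev = group[-1]
            gap = ssr.interval.start - prev.interval.end - 1
            same_seq = ssr.interval.seq_id == prev.interval.seq_id
            if not (same_seq and gap <= compound_max_gap):
                flush()
        group.append(ssr)
    flush()
    return out


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Report-style percentage: half-up rounding, 1 decimal for values
    >= 1%, 2 decimals below 1% (matching the summary-table precision)."""
    if total == 0:
        return 0.0
    pct = 100.0 * count / total
    if 0 < pct < 1:
        return _round_half_up(pct, max(ndigits, 2))
    return _round_half_up(pct, ndigits)


@dataclass
class GenomeSsrSummary:
    """Genome-wide SSR frequency and spectrum summary."""

    total_ssrs: int
    total_bp_examined: int
    density_per_kb: float
    counts_by_motif_size: dict[int, int]
    pct_by_motif_size: dict[int, float]
    counts_by_class: dict[str, int]
    pct_by_class: dict[str, float]
    counts_by_family: dict[str, int]
    compound_count: int

    @property
    def density_rounded(self) -> float:
        return _round_half_up(self.density_per_kb, 3)


def summarize_genome(ssrs: list[SSRLocus],
                     total_bp_examined: int) -> GenomeSsrSummary:
    """Frequency/density summary of one genome's SSR call set.

    Density is SSRs per kb of examined sequence; percentages use half-up
    rounding at report precision while the unrounded density is retained.
    """
    if total_bp_examined <= 0:
        raise ValueError("total_bp_examined must be positive")
    total = len(ssrs)
    counts_size = {k: 0 for k in MOTIF_SIZE_NAMES}
    counts_class = {"I": 0, "II": 0}
    counts_family: dict[str, int] = {}
    compounds: set[str] = set()
    compound_members = 0
    for s in ssrs:
        counts_size[s.motif_size] += 1
        counts_class[s.ssr_class] += 1
        counts_family[s.canonical_family] = (
            counts_family.get(s.canonical_family, 0) + 1
        )
        if s.compound_id is not None:
            compounds.add(s.compound_id)
            compound_members += 1
    density = total / (total_bp_examined / 1000.0)
    return GenomeSsrSummary(
        total_ssrs=total,
        total_bp_examined=total_bp_examined,
        density_per_kb=density,
        counts_by_motif_size=counts_size,
        pct_by_motif_size={k: percent(v, total)
                           for k, v in counts_size.items()},
        counts_by_class=counts_class,
        pct_by_class={k: percent(v, total) for k, v in counts_class.items()},
        counts_by_family=dict(
            sorted(counts_family.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        compound_count=compound_members,
    )


SSR_CATALOG_COLUMNS = [
    "seq_id", "start", "end", "motif", "canonical_family", "motif_size",
    "repeat_count", "tract_length_bp", "class", "compound_id",
]


def ssr_to_row(ssr: SSRLocus) -> dict:
    iv = ssr.interval
    return {
        "seq_id": iv.seq_id,
        "start": iv.start,
        "end": iv.end,
        "motif": ssr.motif,
        "canonical_family": ssr.canonical_family,
        "motif_size": ssr.motif_size,
        "repeat_count": ssr.repeat_count,
        "tract_length_bp": ssr.tract_length_bp,
        "class": ssr.ssr_class,
        "compound_id": ssr.compound_id or "",
    }


def ssr_from_row(row: dict) -> SSRLocus:
    return SSRLocus(
        interval=GenomicInterval(row["seq_id"], int(row["start"]),
                                 int(row["end"])),
        motif=row["motif"],
        canonical_family=row["canonical_family"],
        repeat_count=int(row["repeat_count"]),
        ssr_class=row["class"],
        compound_id=row["compound_id"] or None,
    )
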