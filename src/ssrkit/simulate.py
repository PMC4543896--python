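"""Synthetic genome pairs, gene models and genotype panels with exact truth.

The generator emulates the input structure of a two-assembly SSR marker
study: a pair of closely related genomes that differ only by
expansion/contraction of planted repeat tracts, a GFF3 annotation whose
features place loci into every genomic context, and a marker x individual
genotype panel with known allele frequencies.

Planted truth is exact rather than probabilistic: the background
sequence is made SSR-free by rejection (any window containing a
threshold-exceeding perfect repeat is redrawn), tract boundaries are
fixed so runs cannot extend into the background, and the assembled
genome is re-mined to verify that the planted loci are the only calls.
Motif-family weights default to an AT-rich spectrum (60% AT, 25%
AAT-family, 15% other) and repeat-length differences follow a declining
geometric distribution, mirroring the spectra reported for real legume
genomes; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicInterval, SequenceRecord, write_fasta
from .miner import (MiningParams, canonical_family, find_perfect_ssrs)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: candidate planted motifs per family class
AT_FAMILY = ["AT", "TA"]
AAT_FAMILY = ["AAT", "ATT", "TAA"]
OTHER_MOTIFS = ["AG", "CT", "AAG", "AGG", "AAAT", "AAAG", "AAAAT", "AAAAAT",
                "AATGC"]

DEFAULT_CONTEXT_WEIGHTS = {
    "intergenic": 0.40, "intron": 0.15, "CDS": 0.15,
    "UTR5": 0.05, "UTR3": 0.05, "upstream": 0.20,
}

TRUTH_COLUMNS = [
    "locus_id", "seq_id", "start_a", "end_a", "start_b", "end_b", "motif",
    "canonical_family", "repeat_count_a", "repeat_count_b", "context",
    "gene_id", "polymorphic", "diff_units", "diff_bp", "direction",
]

_SLOT_MIN = 2600  # bp per planted locus: flanks, gene body, upstream window


@dataclass
class SimulationParams:
    """Knobs for :func:`simulate_genome_pair`."""

    n_sequences: int = 1
    sequence_length: int = 160_000
    n_planted_ssrs: int = 50
    fraction_polymorphic: float = 0.4
    motif_family_weights: dict[str, float] = field(
        default_factory=lambda: {"AT": 0.60, "AAT": 0.25, "other": 0.15})
    repeat_count_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {2: (6, 14), 3: (5, 12), 4: (5, 9),
                                 5: (5, 8), 6: (5, 8)})
    diff_unit_geometric_p: float = 0.5
    context_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_WEIGHTS))
    flank_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_polymorphic <= 1:
            raise ValueError("fraction_polymorphic must be in [0, 1]")
        if min(self.n_sequences, self.sequence_length,
               self.n_planted_ssrs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimulatedPair:
    """In-memory result of :func:`simulate_genome_pair`."""

    records_a: list[SequenceRecord]
    records_b: list[SequenceRecord]
    genes: list[GeneModel]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta_a": write_fasta(self.records_a, outdir / "genome_a.fa"),
            "fasta_b": write_fasta(self.records_b, outdir / "genome_b.fa"),
            "gff3": write_gff3(self.genes, outdir / "genes_a.gff3"),
            "truth": outdir / "truth.tsv",
        }
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def write_gff3(genes: list[GeneModel], path: str | Path) -> Path:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            gid = gene.gene_id
            s = gene.span
            attrs = f"ID={gid}"
            out.write(f"{s.seq_id}\tsim\tgene\t{s.start}\t{s.end}\t.\t"
                      f"{s.strand}\t.\t{attrs}\n")
            mid = f"{gid}.1"
            out.write(f"{s.seq_id}\tsim\tmRNA\t{s.start}\t{s.end}\t.\t"
                      f"{s.strand}\t.\tID={mid};Parent={gid}\n")
            rows = (
                [("exon", iv) for iv in gene.exon_parts]
                + [("CDS", iv) for iv in gene.cds_parts]
                + [("five_prime_UTR", iv) for iv in gene.utr5_parts]
                + [("three_prime_UTR", iv) for iv in gene.utr3_parts]
            )
            for ftype, iv in sorted(rows, key=lambda r: (r[1].start,
                                                         r[0])):
                phase = "0" if ftype == "CDS" else "."
                out.write(f"{iv.seq_id}\tsim\t{ftype}\t{iv.start}\t{iv.end}"
                          f"\t.\t{s.strand}\t{phase}\tParent={mid}\n")
    return path


def _random_background(rng: np.random.Generator, length: int,
                       params: MiningParams) -> np.ndarray:
    """Uniform-ACGT sequence with no threshold-exceeding perfect repeat."""
    arr = BASES[rng.integers(0, 4, size=length)]
    for _ in range(200):
        rec = SequenceRecord("bg", arr.tobytes().decode("ascii"))
        calls = find_perfect_ssrs(rec, params)
        if not calls:
            return arr
        for call in calls:
            lo = max(0, call.interval.start - 1)
            hi = min(length, call.interval.end)
            arr[lo:hi] = BASES[rng.integers(0, 4, size=hi - lo)]
    raise RuntimeError("could not draw an SSR-free background")


def _guard_boundaries(arr: np.ndarray, start0: int, end0: int,
                      motif: str) -> None:
    """Fix the bases flanking a planted tract so the perfect run cannot
    extend by even one character in either direction."""
    if start0 > 0 and arr[start0 - 1] == ord(motif[-1]):
        choices = [b for b in BASES if b != ord(motif[-1])]
        arr[start0 - 1] = choices[0]
    if end0 + 1 < len(arr) and arr[end0 + 1] == ord(motif[0]):
        choices = [b for b in BASES if b != ord(motif[0])]
        arr[end0 + 1] = choices[0]


def _draw_motif(rng: np.random.Generator,
                weights: dict[str, float]) -> str:
    labels = list(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    p /= p.sum()
    family = labels[rng.choice(len(labels), p=p)]
    if family == "AT":
        pool = AT_FAMILY
    elif family == "AAT":
        pool = AAT_FAMILY
    else:
        pool = OTHER_MOTIFS
    return pool[rng.integers(0, len(pool))]


def _make_gene(context: str, seq_id: str, t_start: int, t_end: int,
               gene_no: int) -> GeneModel | None:
    """A minimal gene model realising the requested context for a tract
    at [t_start, t_end] (1-based, genome A)."""
    gid = f"gene{gene_no:04d}"

    def iv(a: int, b: int) -> GenomicInterval:
        return GenomicInterval(seq_id, a, b, "+")

    if context == "intergenic":
        return None
    if context == "CDS":
        span = iv(t_start - 100, t_end + 100)
        return GeneModel(gid, span, exon_parts=[span], cds_parts=[span],
                         intron_parts=[])
    if context == "UTR5":
        span = iv(t_start - 100, t_end + 300)
        utr = iv(t_start - 100, t_end + 50)
        cds = iv(t_end + 51, t_end + 300)
        return GeneModel(gid, span, exon_parts=[span], cds_parts=[cds],
                         utr5_parts=[utr], intron_parts=[])
    if context == "UTR3":
        span = iv(t_start - 300, t_end + 100)
        cds = iv(t_start - 300, t_start - 51)
        utr = iv(t_start - 50, t_end + 100)
        return GeneModel(gid, span, exon_parts=[span], cds_parts=[cds],
                         utr3_parts=[utr], intron_parts=[])
    if context == "intron":
        span = iv(t_start - 200, t_end + 200)
        exon1 = iv(t_start - 200, t_start - 101)
        exon2 = iv(t_end + 101, t_end + 200)
        intron = iv(t_start - 100, t_end + 100)
        return GeneModel(gid, span, exon_parts=[exon1, exon2],
                         cds_parts=[exon1, exon2], intron_parts=[intron])
    if context == "upstream":
        span = iv(t_end + 200, t_end + 700)
        return GeneModel(gid, span, exon_parts=[span], cds_parts=[span],
                         intron_parts=[])
    raise ValueError(f"unknown context {context!r}")


def simulate_genome_pair(params: SimulationParams) -> SimulatedPair:
    """Generate a genome pair with planted SSRs and exact truth labels.

    Genome B is genome A with expansions/contractions applied at the
    polymorphic loci (difference in whole repeat units drawn from a
    declining geometric distribution; contracted tracts never drop below
    the mining threshold, so every planted locus is minable in both
    genomes).  Planted loci are spaced > 2.5 kb apart so their 250-bp
    anchor windows are unique and gene models never overlap a
    neighbouring locus.  Raises ValueError when the requested loci do
    not fit the sequence length.
    """
    rng = np.random.default_rng(params.seed)
    mining = MiningParams()
    n_seq = params.n_sequences
    per_seq = [params.n_planted_ssrs // n_seq] * n_seq
    for i in range(params.n_planted_ssrs % n_seq):
        per_seq[i] += 1
    margin = 900
    for count in per_seq:
        if count and (params.sequence_length - 2 * margin) < count * _SLOT_MIN:
            raise ValueError(
                f"cannot pack {count} loci into {params.sequence_length} bp; "
                f"need >= {count * _SLOT_MIN + 2 * margin} bp"
            )

    n_poly = int(round(params.fraction_polymorphic * params.n_planted_ssrs))
    poly_flags = np.zeros(params.n_planted_ssrs, dtype=bool)
    poly_flags[rng.choice(params.n_planted_ssrs, size=n_poly,
                          replace=False)] = True

    context_labels = list(params.context_weights)
    cw = np.array([params.context_weights[c] for c in context_labels],
                  dtype=float)
    cw /= cw.sum()

    records_a: list[SequenceRecord] = []
    records_b: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    locus_no = 0
    gene_no = 0

    for seq_idx in range(n_seq):
        seq_id = f"chr{seq_idx + 1}"
        length = params.sequence_length
        arr = _random_background(rng, length, mining)
        count = per_seq[seq_idx]
        slot = (length - 2 * margin) // count if count else 0
        plan = []  # (start0, motif, r_a, r_b, context)
        for j in range(count):
            motif = _draw_motif(rng, params.motif_family_weights)
            k = len(motif)
            lo, hi = params.repeat_count_range[k]
            r_a = int(rng.integers(lo, hi + 1))
            if poly_flags[locus_no + j]:
                diff = int(rng.geometric(params.diff_unit_geometric_p))
                min_rep = mining.min_repeats[k]
                if rng.random() < 0.5 and r_a - diff >= min_rep:
                    r_b = r_a - diff
                else:
                    r_b = r_a + diff
            else:
                r_b = r_a
            context = context_labels[rng.choice(len(context_labels), p=cw)]
            jitter = int(rng.integers(0, max(1, slot - _SLOT_MIN + 1)))
            start0 = margin + j * slot + 1000 + jitter  # 0-based tract start
            plan.append((start0, motif, r_a, r_b, context))

        # plant genome A tracts
        for start0, motif, r_a, _r_b, _ctx in plan:
            tract = (motif * r_a).encode("ascii")
            end0 = start0 + len(tract) - 1
            arr[start0 : end0 + 1] = np.frombuffer(tract, dtype=np.uint8)
            _guard_boundaries(arr, start0, end0, motif)

        # re-mine and redraw until the planted loci are the only calls
        planted = {(p[0] + 1, p[0] + len(p[1]) * p[2]) for p in plan}
        for _attempt in range(50):
            rec = SequenceRecord(seq_id, arr.tobytes().decode("ascii"))
            extra = [c for c in find_perfect_ssrs(rec, mining)
                     if (c.interval.start, c.interval.end) not in planted]
            if not extra:
                break
            for call in extra:
                lo = max(0, call.interval.start - 1)
                hi = min(length, call.interval.end)
                arr[lo:hi] = BASES[rng.integers(0, 4, size=hi - lo)]
                for start0, motif, r_a, _rb, _c in plan:
                    end0 = start0 + len(motif) * r_a - 1
                    if lo <= end0 + 1 and hi >= start0:
                        tract = (motif * r_a).encode("ascii")
                        arr[start0 : end0 + 1] = np.frombuffer(
                            tract, dtype=np.uint8)
                    _guard_boundaries(arr, start0, end0, motif)
        else:
            raise RuntimeError("failed to isolate planted loci")
        seq_a = arr.tobytes().decode("ascii")

        # genome B: replace tracts, tracking the cumulative coordinate shift
        pieces = []
        cursor = 0
        shift = 0
        b_coords = []
        for start0, motif, r_a, r_b, _ctx in plan:
            end0 = start0 + len(motif) * r_a - 1
            pieces.append(seq_a[cursor:start0])
            b_start0 = start0 + shift
            pieces.append(motif * r_b)
            b_coords.append((b_start0 + 1, b_start0 + len(motif) * r_b))
            shift += len(motif) * (r_b - r_a)
            cursor = end0 + 1
        pieces.append(seq_a[cursor:])
        seq_b = "".join(pieces)
        if params.flank_noise_rate > 0:
            seq_b = _add_flank_noise(rng, seq_b, b_coords,
                                     params.flank_noise_rate, mining)

        records_a.append(SequenceRecord(seq_id, seq_a))
        records_b.append(SequenceRecord(seq_id, seq_b))

        for j, (start0, motif, r_a, r_b, context) in enumerate(plan):
            k = len(motif)
            start_a, end_a = start0 + 1, start0 + k * r_a
            start_b, end_b = b_coords[j]
            gene = _make_gene(context, seq_id, start_a, end_a,
                              gene_no + 1)
            gene_id = ""
            if gene is not None:
                gene_no += 1
                gene_id = gene.gene_id
                genes.append(gene)
            diff_units = abs(r_a - r_b)
            if r_b > r_a:
                direction = "expansion_in_b"
            elif r_b < r_a:
                direction = "contraction_in_b"
            else:
                direction = "equal"
            truth_rows.append({
                "locus_id": f"{seq_id}:{start_a}-{end_a}",
                "seq_id": seq_id,
                "start_a": start_a, "end_a": end_a,
                "start_b": start_b, "end_b": end_b,
                "motif": motif,
                "canonical_family": canonical_family(motif),
                "repeat_count_a": r_a, "repeat_count_b": r_b,
                "context": context, "gene_id": gene_id,
                "polymorphic": diff_units > 0,
                "diff_units": diff_units, "diff_bp": diff_units * k,
                "direction": direction,
            })
        locus_no += count

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedPair(records_a, records_b, genes, truth)


def _add_flank_noise(rng: np.random.Generator, seq: str,
                     tract_coords: list[tuple[int, int]], rate: float,
                     mining: MiningParams) -> str:
    """Sprinkle substitutions outside tracts and a 60-bp guard zone,
    redrawing any substitution that creates a new minable repeat."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    protected = np.zeros(len(arr), dtype=bool)
    for start, end in tract_coords:
        lo = max(0, start - 1 - 60)
        hi = min(len(arr), end + 60)
        protected[lo:hi] = True
    candidates = np.flatnonzero(~protected)
    n_mut = int(len(candidates) * rate)
    sites = rng.choice(candidates, size=n_mut, replace=False)
    for pos in sites:
        alternatives = [b for b in BASES if b != arr[pos]]
        arr[pos] = alternatives[rng.integers(0, 3)]
    rec = SequenceRecord("noisy", arr.tobytes().decode("ascii"))
    calls = find_perfect_ssrs(rec, mining)
    expected = {(s, e) for s, e in tract_coords}
    for call in calls:
        if (call.interval.start, call.interval.end) not in expected:
            # revert the noisy window rather than risk a spurious locus
            lo, hi = call.interval.start - 1, call.interval.end
            arr[lo:hi] = np.frombuffer(
                seq.encode("ascii"), dtype=np.uint8)[lo:hi]
    return arr.tobytes().decode("ascii")


def simulate_genotype_matrix(n_markers: int, n_individuals: int,
                             allele_count_range: tuple[int, int] = (2, 8),
                             dirichlet_alpha: float = 3.0,
                             missing_rate: float = 0.0,
                             seed: int | None = None):
    """Genotype panel with known truth frequencies.

    Per marker, the allele count is uniform on ``allele_count_range``,
    allele frequencies are a symmetric Dirichlet draw, and individual
    calls are i.i.d. samples.  Allele labels are fragment sizes in bp.
    Returns ``(GenotypeMatrix, truth)`` where truth maps marker id to
    its {allele: frequency} dict.
    """
    from .stats import GenotypeMatrix

    if n_markers < 1 or n_individuals < 1:
        raise ValueError("need at least one marker and one individual")
    rng = np.random.default_rng(seed)
    markers = [f"M{i + 1:04d}" for i in range(n_markers)]
    individuals = [f"G{j + 1:03d}" for j in range(n_individuals)]
    data = np.zeros((n_markers, n_individuals))
    truth: dict[str, dict[int, float]] = {}
    lo, hi = allele_count_range
    for i, marker in enumerate(markers):
        n_alleles = int(rng.integers(lo, hi + 1))
        sizes = [100 + 10 * i % 200 + 2 * a for a in range(n_alleles)]
        freqs = rng.dirichlet([dirichlet_alpha] * n_alleles)
        truth[marker] = {s: float(f) for s, f in zip(sizes, freqs)}
        draws = rng.choice(n_alleles, size=n_individuals, p=freqs)
        data[i] = [sizes[d] for d in draws]
    df = pd.DataFrame(data, index=markers, columns=individuals)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return GenotypeMatrix(df), truth
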