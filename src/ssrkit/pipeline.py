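"""End-to-end pipeline: mine both genomes, annotate, anchor, call, export.

A :class:`PipelineConfig` collects the file paths and the method
constants (mining thresholds, 250-bp anchor flanks, E <= 1e-40
reciprocal-unique filtering, >= 2 bp polymorphism call, >= 4 bp
validation subset, 1000-bp upstream windows).  Every stage persists its
intermediate as TSV under the run directory and the final
:class:`RunReport` aggregates the counts the study tables report.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .anchor import (DEFAULT_EVALUE_MAX, DEFAULT_FLANK_LEN, anchor_loci)
from .annotate import annotate_locus, build_feature_index, context_breakdown
from .io import read_alignment_table, read_fasta, read_gff3, write_tsv_catalog
from .miner import (GenomeSsrSummary, MiningParams, SSR_CATALOG_COLUMNS,
                    find_perfect_ssrs, merge_compound, percent, ssr_to_row,
                    summarize_genome)
from .polymorph import (DEFAULT_MIN_DIFF_BP, VALIDATION_MIN_DIFF_BP,
                        bin_differences, call_all, export_catalog,
                        export_primer_targets, select_validation_set)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta_a: Path
    fasta_b: Path
    gff_a: Path | None = None
    gff_b: Path | None = None
    hits_ab: Path | None = None
    hits_ba: Path | None = None
    outdir: Path = Path("ssrkit_run")
    min_repeats: dict[int, int] = field(
        default_factory=lambda: {2: 6, 3: 5, 4: 5, 5: 5, 6: 5})
    compound_gap: int = 100
    flank_len: int = DEFAULT_FLANK_LEN
    evalue_max: float = DEFAULT_EVALUE_MAX
    min_diff: int = DEFAULT_MIN_DIFF_BP
    validation_min_diff: int = VALIDATION_MIN_DIFF_BP
    upstream_len: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("fasta_a", "fasta_b", "gff_a", "gff_b",
                     "hits_ab", "hits_ba"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        if self.flank_len <= 0 or self.upstream_len <= 0:
            raise ValueError("flank_len and upstream_len must be positive")
        if self.evalue_max < 0 or self.min_diff < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        kwargs = {}
        for key, value in raw.items():
            if key in ("fasta_a", "fasta_b", "gff_a", "gff_b", "hits_ab",
                       "hits_ba", "outdir"):
                kwargs[key] = Path(value)
            elif key == "min_repeats":
                kwargs[key] = {int(k): int(v) for k, v in value.items()}
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RunReport:
    summary_a: GenomeSsrSummary
    summary_b: GenomeSsrSummary
    n_queries_a: int
    n_queries_b: int
    n_pairs: int
    n_polymorphic: int
    n_monomorphic: int
    n_rejected: int
    diff_histogram: dict[str, int]
    context_counts: dict[str, int]
    n_validation: int
    version: str = __version__


def format_count_pct(count: int, total: int) -> str:
    """Table-style "count (pct)" cell, e.g. ``41457 (55.3)``.

    One decimal place, except two decimals for percentages below 1.
    """
    p = percent(count, total)
    decimals = 2 if 0 < p < 1 else 1
    return f"{count} ({p:.{decimals}f})"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute mine x2 -> annotate -> anchor -> call -> select -> export."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = MiningParams(min_repeats=dict(config.min_repeats),
                          compound_max_gap=config.compound_gap)

    logger.info("stage mine: genome A")
    genome_a = {r.id: r for r in read_fasta(config.fasta_a)}
    ssrs_a = _mine_genome(genome_a, params)
    logger.info("stage mine: genome B")
    genome_b = {r.id: r for r in read_fasta(config.fasta_b)}
    ssrs_b = _mine_genome(genome_b, params)
    write_tsv_catalog([ssr_to_row(s) for s in ssrs_a], SSR_CATALOG_COLUMNS,
                      outdir / "ssrs_a.tsv")
    write_tsv_catalog([ssr_to_row(s) for s in ssrs_b], SSR_CATALOG_COLUMNS,
                      outdir / "ssrs_b.tsv")
    summary_a = summarize_genome(ssrs_a, sum(len(r.seq)
                                             for r in genome_a.values()))
    summary_b = summarize_genome(ssrs_b, sum(len(r.seq)
                                             for r in genome_b.values()))

    logger.info("stage annotate")
    contexts = {}
    if config.gff_a is not None:
        genes = read_gff3(config.gff_a)
        seq_lengths = {r.id: len(r.seq) for r in genome_a.values()}
        index = build_feature_index(genes, upstream_len=config.upstream_len,
                                    seq_lengths=seq_lengths)
        contexts = {s.locus_id: annotate_locus(s, index, seq_lengths)
                    for s in ssrs_a}

    logger.info("stage anchor")
    hits_ab = (read_alignment_table(config.hits_ab)
               if config.hits_ab else None)
    hits_ba = (read_alignment_table(config.hits_ba)
               if config.hits_ba else None)
    pairs = anchor_loci(ssrs_a, genome_a, ssrs_b, genome_b,
                        flank_len=config.flank_len,
                        evalue_max=config.evalue_max,
                        hits_ab=hits_ab, hits_ba=hits_ba)

    logger.info("stage call")
    calls, rejected = call_all(pairs, min_diff_bp=config.min_diff,
                               contexts=contexts)
    polymorphic = [c for c in calls if c.polymorphic]
    export_catalog(polymorphic, outdir / "polymorphic_catalog.tsv")
    export_catalog(calls, outdir / "all_calls.tsv")

    logger.info("stage select + export")
    validation = select_validation_set(polymorphic,
                                       config.validation_min_diff)
    export_catalog(validation, outdir / "validation_set.tsv")
    export_primer_targets(polymorphic, genome_a,
                          outdir / "primer_targets.boulder",
                          flank_len=config.flank_len)

    hist = bin_differences(polymorphic)
    annotated = [(c.pair.locus_a, c.context) for c in polymorphic
                 if c.context is not None]
    ctx_counts = (context_breakdown(annotated).counts if annotated
                  else {})
    report = RunReport(
        summary_a=summary_a,
        summary_b=summary_b,
        n_queries_a=len(ssrs_a),
        n_queries_b=len(ssrs_b),
        n_pairs=len(pairs),
        n_polymorphic=len(polymorphic),
        n_monomorphic=len(calls) - len(polymorphic),
        n_rejected=len(rejected),
        diff_histogram=hist,
        context_counts=ctx_counts,
        n_validation=len(validation),
    )
    (outdir / "report.txt").write_text(render_report(report))
    return report


def _mine_genome(genome, params: MiningParams):
    ssrs = []
    for rec in genome.values():
        found = find_perfect_ssrs(rec, params)
        ssrs.extend(merge_compound(found, params.compound_max_gap))
    return ssrs


def render_report(report: RunReport) -> str:
    """Human-readable run summary in the study's table style."""
    lines = [f"ssrkit v{report.version} run report", ""]
    for label, s in (("genome A", report.summary_a),
                     ("genome B", report.summary_b)):
        lines += [
            f"[{label}]",
            f"  total SSRs: {s.total_ssrs}",
            f"  bp examined: {s.total_bp_examined}",
            f"  density: {s.density_rounded:.3f} SSR/kb",
        ]
        for size, name in ((2, "di"), (3, "tri"), (4, "tetra"),
                           (5, "penta"), (6, "hexa")):
            lines.append(
                f"  {name}-nucleotides: "
                + format_count_pct(s.counts_by_motif_size[size],
                                   s.total_ssrs))
        for cls in ("I", "II"):
            lines.append(f"  class {cls}: "
                         + format_count_pct(s.counts_by_class[cls],
                                            s.total_ssrs))
        lines.append(f"  in compound formation: {s.compound_count}")
        lines.append("")
    lines += [
        "[anchoring]",
        f"  reciprocal unique pairs: {report.n_pairs}",
        "",
        "[polymorphism]",
        f"  polymorphic: {report.n_polymorphic}",
        f"  monomorphic: {report.n_monomorphic}",
        f"  rejected (family mismatch): {report.n_rejected}",
        f"  validation subset (>= 4 bp): {report.n_validation}",
        "  difference histogram (bp: count): "
        + ", ".join(f"{k}:{v}" for k, v in report.diff_histogram.items()
                    if v),
    ]
    if report.context_counts:
        lines += ["", "[contexts of polymorphic SSRs]"]
        for ctx, count in report.context_counts.items():
            if count:
                lines.append("  " + ctx + ": "
                             + format_count_pct(count,
                                                report.n_polymorphic))
    return "\n".join(lines) + "\n"
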