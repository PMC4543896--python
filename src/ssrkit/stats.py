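"""Marker informativeness and diversity statistics from genotype panels.

The genotype model is haploid-equivalent: chickpea is highly selfing, so
each individual contributes a single allele (fragment size in bp) per
marker locus; heterozygous cells are rejected at load.  From the allele
frequencies the module computes, per marker,

* gene diversity (expected heterozygosity)  ``H = 1 - sum p_i^2``
* polymorphism information content (Botstein convention, as produced by
  PowerMarker)  ``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``

and across individuals Nei's (1972) standard genetic distance.  With
single-allele profiles the within-population identities are 1 and the
distance reduces to ``D(x, y) = -ln(proportion of shared loci)`` over
loci typed in both individuals.  Trees are built with neighbor joining
(Saitou-Nei) and bootstrapped by resampling marker loci.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

logger = logging.getLogger(__name__)

MISSING = {"", "NA", "N/A", "NaN", "nan", ".", "-"}


@dataclass
class GenotypeMatrix:
    """Marker x individual allele-size table with explicit missing data."""

    data: pd.DataFrame  # rows = markers, columns = individuals, float + NaN

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("genotype matrix is empty")
        values = self.data.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if (finite <= 0).any() or (finite != np.round(finite)).any():
            raise ValueError("allele sizes must be positive integers (bp)")

    @property
    def markers(self) -> list[str]:
        return list(self.data.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None
                  ) -> "GenotypeMatrix":
        """Load a TSV/CSV genotype table (rows markers, columns
        individuals).  Cells must be single allele sizes or NA;
        heterozygous calls like ``200/204`` raise ValueError."""
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          keep_default_na=False)
        parsed = pd.DataFrame(index=raw.index, columns=raw.columns,
                              dtype=float)
        for marker in raw.index:
            for ind in raw.columns:
                cell = str(raw.at[marker, ind]).strip()
                if cell in MISSING:
                    parsed.at[marker, ind] = np.nan
                elif "/" in cell or "|" in cell:
                    raise ValueError(
                        f"heterozygous call {cell!r} at ({marker}, {ind}): "
                        "this toolkit models one allele per individual"
                    )
                else:
                    parsed.at[marker, ind] = float(cell)
        return cls(parsed)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out.index.name = "marker"
        formatted = out.map(
            lambda v: "" if pd.isna(v) else str(int(v)))
        formatted.to_csv(path, sep="\t", na_rep="")
        return path


def allele_frequencies(matrix: GenotypeMatrix, marker: str
                       ) -> dict[int, float]:
    """Allele frequencies among non-missing calls for one marker."""
    row = matrix.data.loc[marker].dropna()
    if row.empty:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    counts = row.value_counts()
    total = counts.sum()
    return {int(allele): count / total for allele, count in counts.items()}


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict)
                   else freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def pic(freqs) -> float:
    """Polymorphism information content (Botstein et al. convention).

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  Zero for a
    monomorphic marker; always <= gene diversity.
    """
    p = _check_freqs(freqs)
    sum_sq = float(np.sum(p ** 2))
    sum_4 = float(np.sum(p ** 4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sum_sq - (sum_sq ** 2 - sum_4)


def gene_diversity(freqs) -> float:
    """Expected heterozygosity 1 - sum p_i^2."""
    p = _check_freqs(freqs)
    return 1.0 - float(np.sum(p ** 2))


@dataclass(frozen=True)
class MarkerSummary:
    marker_id: str
    n_alleles: int
    polymorphic: bool
    pic: float
    gene_diversity: float


@dataclass
class PanelSummary:
    markers: list[MarkerSummary]
    total_alleles: int
    mean_alleles_per_locus: float
    percent_polymorphic: float
    mean_pic: float
    mean_gene_diversity: float
    group_summaries: dict[str, "PanelSummary"] | None = None


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_markers(matrix: GenotypeMatrix,
                      groups: dict[str, str] | None = None) -> PanelSummary:
    """Per-marker allele counts, PIC and gene diversity, plus panel
    aggregates.  A marker is polymorphic when it shows >= 2 distinct
    non-missing alleles.  ``groups`` maps individual -> subgroup label
    and triggers subgroup aggregates over the same markers.
    """
    summaries: list[MarkerSummary] = []
    for marker in matrix.markers:
        freqs = allele_frequencies(matrix, marker)
        n_alleles = len(freqs)
        summaries.append(MarkerSummary(
            marker_id=marker,
            n_alleles=n_alleles,
            polymorphic=n_alleles >= 2,
            pic=pic(freqs),
            gene_diversity=gene_diversity(freqs),
        ))
    n = len(summaries)
    total_alleles = sum(s.n_alleles for s in summaries)
    n_poly = sum(s.polymorphic for s in summaries)
    panel = PanelSummary(
        markers=summaries,
        total_alleles=total_alleles,
        mean_alleles_per_locus=total_alleles / n,
        percent_polymorphic=100.0 * n_poly / n,
        mean_pic=sum(s.pic for s in summaries) / n,
        mean_gene_diversity=sum(s.gene_diversity for s in summaries) / n,
    )
    if groups:
        by_label: dict[str, list[str]] = {}
        for ind, label in groups.items():
            by_label.setdefault(label, []).append(ind)
        panel.group_summaries = {}
        for label, inds in sorted(by_label.items()):
            sub = GenotypeMatrix(matrix.data[inds])
            panel.group_summaries[label] = summarize_markers(sub)
    return panel


def mean_alleles_report(total_alleles: int, n_markers: int) -> float:
    """Report-precision mean alleles per locus (half-up, 1 decimal)."""
    return _round_half_up(total_alleles / n_markers, 1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with "
                             "zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def nei_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between individuals.

    With one allele per individual per locus the identities J_x and J_y
    are 1 and D(x, y) = -ln(fraction of pairwise-complete loci at which
    x and y carry the same allele).  A pair sharing no allele at any
    comparable locus has infinite distance; such cells are reported as
    the largest finite distance in the matrix plus 1 and logged.
    """
    inds = matrix.individuals
    if len(inds) < 2:
        raise ValueError("need at least 2 individuals")
    values = matrix.data.to_numpy(dtype=float)
    n = len(inds)
    dist = np.zeros((n, n))
    infinite_pairs: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            n_loci = int(both.sum())
            if n_loci == 0:
                raise ValueError(
                    f"individuals {inds[i]!r} and {inds[j]!r} share no "
                    "typed loci"
                )
            shared = float((values[both, i] == values[both, j]).sum())
            if shared == 0:
                dist[i, j] = dist[j, i] = np.inf
                infinite_pairs.append((inds[i], inds[j]))
            else:
                d = -math.log(shared / n_loci)
                dist[i, j] = dist[j, i] = d
    if infinite_pairs:
        finite = dist[np.isfinite(dist)]
        cap = (finite.max() if finite.size else 0.0) + 1.0
        shown = infinite_pairs[:5]
        logger.warning("%d pair(s) share no alleles; distance capped at "
                       "%.4f (e.g. %s)", len(infinite_pairs), cap, shown)
        dist[np.isinf(dist)] = cap
    return DistanceMatrix(ids=list(inds), values=dist)


def neighbor_joining(dist: DistanceMatrix,
                     neg_as_zero: bool = False) -> TreeNode:
    """Neighbor-joining (Saitou-Nei) unrooted tree from a distance matrix.

    Negative branch lengths are retained by default and clamped to zero
    only when writing Newick (see :func:`write_newick`).
    """
    if len(dist.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = _SkbioDM(dist.values, ids=dist.ids)
    return _skbio_nj(dm, neg_as_zero=neg_as_zero)


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    smaller/lexicographically-first side's tip-name frozenset."""
    tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            canon = min(side, other, key=lambda s: (len(s), sorted(s)))
            parts.add(canon)
    return parts


def bootstrap_support(matrix: GenotypeMatrix, n_reps: int = 1000,
                      seed: int | None = None,
                      distance_fn=nei_distance) -> TreeNode:
    """NJ tree with bootstrap supports from marker-column resampling.

    Marker loci are resampled with replacement ``n_reps`` times; each
    internal edge of the full-data tree is labelled with the percentage
    of replicate trees containing the same bipartition.  Deterministic
    for a fixed seed; ``n_reps=0`` returns the unlabelled tree.
    """
    if len(matrix.individuals) < 3 or len(matrix.markers) < 2:
        raise ValueError("need >= 3 individuals and >= 2 markers")
    tree = neighbor_joining(distance_fn(matrix))
    if n_reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    n_markers = len(matrix.markers)
    counts: dict[frozenset[str], int] = {}
    target = tree_bipartitions(tree)
    for part in target:
        counts[part] = 0
    # replicate-level distance caps would repeat the same warning n_reps
    # times; the full-data tree above already reported it once
    rep_level = logger.level
    logger.setLevel(logging.ERROR)
    try:
        for _ in range(n_reps):
            idx = rng.integers(0, n_markers, size=n_markers)
            resampled = matrix.data.iloc[idx]
            resampled = resampled.set_axis(
                [f"m{i}" for i in range(n_markers)], axis=0)
            try:
                rep_tree = neighbor_joining(
                    distance_fn(GenotypeMatrix(resampled)))
            except ValueError:
                continue  # replicate left some pair with no comparable loci
            rep_parts = tree_bipartitions(rep_tree)
            for part in target & rep_parts:
                counts[part] += 1
    finally:
        logger.setLevel(rep_level)
    tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not 1 < len(side) < len(tips) - 1:
            continue
        canon = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(canon, 0) / n_reps
        node.name = f"{support:g}"
    return tree


def write_newick(tree: TreeNode, path: str | Path,
                 clamp_negative: bool = True) -> Path:
    """Write Newick; negative NJ branch lengths are clamped to 0 (logged)."""
    path = Path(path)
    clamped = 0
    if clamp_negative:
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
                clamped += 1
    if clamped:
        logger.warning("clamped %d negative branch length(s) to 0", clamped)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    path.write_text(buf.getvalue())
    return path


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    dm = tree.cophenet()
    ids = list(dm.ids)
    return DistanceMatrix(ids=ids, values=np.asarray(dm.data, dtype=float))
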