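# Methods

## Repeat model and mining

A perfect SSR is a run of identical copies of a 2–6 nt motif.
Detection decomposes each sequence, for each motif size *k*, into
character-maximal *k*-periodic regions (maximal stretches with
`s[j] == s[j+k]`; any non-ACGT symbol breaks a region). Each region
yields at most one tract: the leftmost run of whole motif copies.
Partial trailing units are discarded, so tract length is always a
multiple of the motif size — a deliberate choice, because downstream
polymorphism is measured in whole repeat units. A motif that is a power
of a shorter unit is never reported; such regions surface at their
primitive period, which is what resolves overlap between motif sizes
(an AT run is a di-nucleotide SSR, never an ATAT tetra-nucleotide one).

Thresholds (configurable via `MiningParams`):

| parameter | default | meaning |
|---|---|---|
| `min_repeats` | {2: 6, 3: 5, 4: 5, 5: 5, 6: 5} | min whole units per motif size |
| `compound_max_gap` | 100 bp | max gap between members of a compound SSR |
| class I boundary | ≥ 20 bp | hypervariable class |
| class II range | 12 to < 20 bp | potentially variable class |

The class boundary at exactly 20 bp is assigned to class I (the class
with the explicit ≥ definition); the two published class definitions
overlap at 20 bp, so this had to be fixed by convention. Under these
thresholds class II can only contain di- and tri-nucleotide tracts
(tetra-nucleotides already reach 20 bp at 5 units).

Motifs are normalised to a canonical family label: the
lexicographically smallest rotation among the motif's rotations and its
reverse complement's rotations (TA, AT → AT; ATT, TAA → AAT). Report
percentages round half-up to 1 decimal (2 decimals below 1%) and
densities to 3 decimals, matching genome-survey table precision; the
unrounded values are kept internally.

## Structural annotation

Each locus receives exactly one primary context: CDS, 5′-UTR, 3′-UTR,
intron, upstream or intergenic, decided by the feature containing the
**tract midpoint** (`(start+end)//2`), with ties broken by the
precedence CDS > UTR5 > UTR3 > intron > upstream > intergenic and, at
equal precedence, by the gene earliest in coordinate order (logged).
The midpoint rule is deterministic and symmetric for boundary-straddling
tracts; no published rule exists for straddlers, so this is a design
choice. Upstream windows are 1000 bp 5′ of the gene start,
strand-aware, truncated at sequence ends. "Exon" is reported as a
derived super-category (CDS ∪ UTRs), since exon and CDS counts are
conventionally reported side by side as distinct numbers. When an
annotation lacks UTR features, exonic non-CDS sequence is labelled
`UTR_unknown` and counted under exon. Genes are read from GFF3 with
exons unioned across transcripts and CDS/UTRs taken from the
longest-CDS transcript.

## Ortholog anchoring

Each locus contributes a query window of up to 250 bp of flank on each
side with the tract hard-masked to N. Masking keeps the window
contiguous while guaranteeing that the quantity later measured (tract
length) cannot contribute alignment score and bias the matching.

The built-in aligner is an ungapped seed-and-extend matcher intended
for simulated and desk-scale data: maximal exact seeds of ≥ 50 bp,
X-drop ungapped extension (match +2, mismatch −3, drop 12), both
strands, all distinct maximal extensions reported. Its E-value is a
surrogate, `E = m·n·2^(−S)` with `S = 2·matches − 3·mismatches`; it is
*not* a Karlin–Altschul calibration and is documented as such. For real
genomes, run BLASTN externally on the exported query FASTA
(`ssrkit export-queries`) and feed the 12-column tabular hits back in —
the reciprocal filter accepts either source interchangeably.

Reciprocal unique filtering: a hit "lands on" a window when its
subject interval overlaps the window by ≥ 50% of the hit length. A
query is unambiguous when all of its hits with E ≤ 1e-40 land on one
and the same window of the other genome; a passing hit landing on no
window, or on a second window, disqualifies the query. A pair is kept
when A's unique target is B and B's unique target is A, which makes the
mapping one-to-one. Uniqueness is deliberately defined at the *window*
level rather than the raw-hit level: when tract lengths differ between
genomes, the two flanks of one window necessarily align on different
diagonals and produce two ungapped hits on the same target window;
counting raw hits would disqualify every truly polymorphic locus.

## Polymorphism calling

At an anchored pair with matching canonical motif families (mismatching
families are set aside as rejected records, not errors),
`diff_units = |r_A − r_B|` and `diff_bp = diff_units × motif length`.
A locus is polymorphic when `diff_bp ≥ 2` (the smallest observable
change under the perfect-repeat model: one di-nucleotide unit);
differences are binned 2..20 bp plus an open "> 20" bin, and the
declining frequency-vs-length trend is reported. The validation subset
uses `diff_bp ≥ 4`, the threshold used when selecting markers for
wet-lab screening. Direction is reported relative to genome B
(`expansion_in_b` / `contraction_in_b`); both repeat counts are in the
catalog so either orientation can be re-derived. Contexts attach from
the genome A annotation, because primer templates come from genome A.

Primer targets are exported as Boulder-IO records with the unmasked
genome A window as `SEQUENCE_TEMPLATE` and the tract as
`SEQUENCE_TARGET=<start>,<length>`. Offsets are 1-based and every
record carries `PRIMER_FIRST_BASE_INDEX=1` so Primer3 interprets them
identically. No primer picking is done in-process.

## Marker statistics

Genotype panels are haploid-equivalent: one allele (fragment size, bp)
per individual per marker, reflecting a predominantly selfing species
scored on homozygous lines; heterozygous cells are rejected at load.
Frequencies are computed over non-missing calls. Gene diversity is
`H = 1 − Σ pᵢ²`; PIC is the Botstein form
`1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²` (the convention implemented by
PowerMarker), so `PIC ≤ H` always, with equality only at 0.

Nei's (1972) standard distance between two single-allele profiles
reduces to `D(x,y) = −ln(proportion of shared loci)` over loci typed in
both individuals (the within-individual identities are 1 under the
homozygous model). A pair sharing no allele at any comparable locus has
infinite distance; such cells are capped at the largest finite distance
in the matrix plus 1 and logged — the cap keeps the matrix usable for
tree building while flagging the saturation. The unbiased 1978
correction is out of scope here since individuals, not populations, are
the profiles.

Trees are neighbor-joining (Saitou–Nei, via scikit-bio) on the Nei
matrix. Negative branch lengths are retained in the data model and
clamped to zero only at Newick export (logged). Bootstrap resamples
marker columns with replacement (standard practice for marker trees);
each internal edge of the full-data tree is labelled with the
percentage of replicates whose tree contains the same bipartition.
A single seed makes the procedure deterministic.

## Synthetic data generator

`simulate_genome_pair` emulates the input structure of a two-assembly
comparison with *exact* truth:

* the background is uniform ACGT made SSR-free by rejection (windows
  containing any threshold-exceeding perfect repeat are redrawn), and
  after planting, the assembled sequence is re-mined to verify the
  planted loci are the *only* calls — so miner sensitivity/precision
  against truth is exactly 100% by construction, not probabilistically;
* tract boundaries are guarded (the flanking base never extends the
  repeat period) and loci are spaced > 2.5 kb apart so 250 bp anchor
  windows are unique and per-locus gene models never collide;
* genome B applies expansions/contractions at the polymorphic fraction
  of loci (default 0.4): unit differences follow a declining geometric
  distribution (p = 0.5), contraction never drops a tract below the
  mining threshold, and coordinates shift accordingly;
* motif families default to 60% AT, 25% AAT-family, 15% other,
  mirroring the AT-rich spectra of legume genomes; contexts default to
  intergenic-dominated proportions with every context class exercised;
* optional flank noise (default off) applies 1% substitutions outside a
  60 bp guard zone around tracts, reverting any substitution that
  creates a new minable repeat.

What the generator does **not** emulate: indels in flanks, imperfect or
compound-by-mutation repeats, transposable-element context, scaffold
fragmentation, or realistic coalescent divergence. Passing the planted
recovery suite therefore demonstrates the pipeline's bookkeeping and
filtering are exact under clean conditions, not that real-genome recall
matches it — real runs inherit BLASTN's sensitivity and the assemblies'
quality.

`simulate_genotype_matrix` draws per-marker allele counts uniformly
(default 2–8), frequencies from a symmetric Dirichlet (default α = 3 —
chosen so the expected panel diversity matches validated SSR panels,
E[H] ≈ 0.75 at 5 alleles), and i.i.d. individual calls; truth
frequencies are returned alongside.

Default simulation scale (1 sequence × 160 kb, 50 loci; panels of tens
of markers × 46–500 individuals) keeps the full test suite and the
acceptance script in the seconds-to-a-minute range while exercising
every code path.

## Numerical and edge-case conventions

* Coordinates are 1-based inclusive everywhere in outputs; interval
  length is `end − start + 1`.
* Report rounding is decimal half-up (not banker's), via `Decimal`.
* The miner returns loci sorted by start, ties by motif size; compound
  grouping requires sorted input and raises otherwise.
* Frequency vectors must sum to 1 within 1e-9; negative frequencies
  raise.
* Surrogate E-values below ~1e-308 underflow to exactly 0.0, which is
  reported as such (a verbatim full-window match prints E = 0).
* `GenotypeMatrix` requires positive integer allele sizes; all-missing
  markers raise on frequency computation.

## Known limitations

* The built-in aligner is ungapped: an indel in a flank splits hits and
  can fail the 50%-overlap landing rule; use external BLASTN for real
  data.
* One statistical property is knowingly strict: requiring the plug-in
  gene diversity of *every* marker to sit within 0.02 of truth at
  n = 500 individuals is at the same order as the estimator's sampling
  standard deviation (up to ~0.02 for skewed two-allele markers), so
  that check can fail by sampling noise alone; the mean-error checks
  are the stable ones.
* Percent values below 1 are reported at two decimals with half-up
  rounding; published tables sometimes truncate instead, which can
  differ in the last digit (e.g. 0.98744% → 0.99 here).
* UTR-less annotations push exonic non-CDS loci into `UTR_unknown`
  rather than guessing UTR sidedness from strand and CDS position.
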