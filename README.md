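# ssrkit

Comparative microsatellite (SSR) marker development for pairs of related
genome assemblies, modelled on the workflow used to build genome-wide
polymorphic SSR marker panels for *desi* and *kabuli* chickpea.

`ssrkit` is aimed at plant molecular breeders and genome scientists who
have two assemblies of closely related genotypes (cultivars, subspecies,
parental lines) plus a gene annotation, and want a catalog of SSR loci
whose repeat length differs between the two — the loci most likely to be
polymorphic, PCR-genotypable markers.

## What it does

1. **Mine** perfect SSRs from each assembly with MISA-style criteria:
   at least 6 repeats of a di-nucleotide motif or 5 repeats of a
   tri- to hexa-nucleotide motif; mononucleotide runs excluded. Tracts
   ≥ 20 bp are hypervariable **class I**, 12 to < 20 bp **class II**;
   nearby SSRs (≤ 100 bp apart) are flagged as compound.
2. **Annotate** each locus into one genomic context — CDS, 5′-UTR,
   3′-UTR, intron, upstream (1000 bp 5′ of a gene) or intergenic —
   from a GFF3 annotation.
3. **Anchor** orthologous loci across the two assemblies: a 250 bp
   flank window on each side of the tract (tract hard-masked to N) is
   aligned against the other genome, and a pair is kept only when the
   windows are each other's *reciprocal unique hit* at E ≤ 1e-40.
   A built-in seed-and-extend aligner handles simulated and desk-scale
   data; genome-scale runs import external BLASTN `-outfmt 6` tables.
4. **Call polymorphism** at anchored loci from the difference in whole
   repeat units: diff\_bp = |r_A − r_B| · motif length, binned
   2..20 and "\>20". A validation subset (diff ≥ 4 bp) and Boulder-IO
   primer-design targets for Primer3 are exported.
5. **Evaluate markers** from a genotype panel (marker × individual
   allele sizes, one allele per individual — a selfing-species model):
   allele counts, percent polymorphism, gene diversity
   *H* = 1 − Σpᵢ², polymorphism information content
   *PIC* = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein convention), Nei's (1972)
   genetic distance *D* = −ln(shared-allele proportion), and a
   neighbor-joining tree with marker-bootstrap supports.

A synthetic-data module generates genome pairs with planted SSR
expansions, matching GFF3 gene models and genotype panels with known
allele frequencies, each with a machine-readable truth table — so the
whole pipeline is testable offline against exact expectations.

## Worked example

Simulate a genome pair (1 × 160 kb sequence, 50 planted SSR loci of
which 20 carry repeat expansions/contractions) and run the pipeline:

```sh
ssrkit simulate genome-pair --seed 7 -o demo
cat > demo/config.toml <<EOF
fasta_a = "demo/genome_a.fa"
fasta_b = "demo/genome_b.fa"
gff_a = "demo/genes_a.gff3"
outdir = "demo/run"
EOF
ssrkit run --config demo/config.toml
```

which prints (abridged):

```
[genome A]
  total SSRs: 50
  bp examined: 160000
  density: 0.313 SSR/kb
  di-nucleotides: 32 (64.0)
  tri-nucleotides: 16 (32.0)
  ...
[anchoring]
  reciprocal unique pairs: 50
[polymorphism]
  polymorphic: 20
  monomorphic: 30
  validation subset (>= 4 bp): 12
  difference histogram (bp: count): 2:5, 3:3, 4:6, 6:4, 9:1, 12:1
[contexts of polymorphic SSRs]
  upstream: 6 (30.0)
  intergenic: 7 (35.0)
  ...
```

All 50 planted loci are mined in both genomes, all 50 ortholog pairs
are anchored, and the 20 planted expansions are called polymorphic with
their exact bp differences — counts that match the simulator's truth
table row for row. Cells are printed `count (percent)` with half-up
rounding to one decimal (two decimals below 1%), and density to three
decimals, the conventions of genome-wide SSR summary tables.

Marker statistics from a genotype panel:

```sh
ssrkit simulate genotypes -m 12 -n 10 --seed 3 -o demo/panel.tsv
ssrkit stats --genotypes demo/panel.tsv -o demo/summary.tsv
# 12 markers, 46 alleles (mean 3.8/locus), 100.0% polymorphic,
#   mean PIC 0.57 -> demo/summary.tsv
ssrkit tree --genotypes demo/panel.tsv --bootstrap 1000 --seed 7 -o demo/tree.nwk
```

`summary.tsv` lists per marker the allele count, polymorphic flag, PIC
and gene diversity, e.g. `M0001  4  true  0.4500  0.4800`: four alleles
whose frequencies give H = 0.48 and PIC = 0.45 (PIC ≤ H always).

## Command reference

`mine`, `annotate`, `export-queries`, `anchor`, `call-poly`, `select`,
`export-primers`, `stats`, `tree`, `simulate genome-pair`,
`simulate genotypes`, `run` — see `ssrkit <cmd> --help`. All stages are
also importable library functions (`ssrkit.find_perfect_ssrs`,
`ssrkit.anchor_loci`, `ssrkit.nei_distance`, ...).

See `docs/methods.md` for the model, parameter defaults, the synthetic
data generator's assumptions, and known limitations.
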