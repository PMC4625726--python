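# mitoasym

Tools for the computational side of a mitochondrial-genome study:
annotation-table arithmetic, strand-asymmetry and codon-usage statistics, a
pileup-based heteroplasmy caller with codon-level effect annotation, and a
synthetic mitogenome/read simulator so the whole pipeline is testable
without downloads.

The package grew out of the analysis of the 17,271-bp circular mitogenome of
the South American annual killifish *Austrolebias charrua* (GenBank
KP718940): 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one control
region, with the strongest strand asymmetry reported among cyprinodontiform
fishes and heteroplasmic variants segregating among full siblings. It is
aimed at anyone who has an annotated mitogenome (or wants to simulate one)
and deep short-read data and needs the derived numbers a mitogenome paper
prints: gene sizes and intergenic spacers, skews and codon-position GC,
codon usage ordinations, and a conservative list of sub-clonal variants.

## What it computes

**Annotation arithmetic.** Features are 1-based closed intervals on the H
strand. For a CDS of n nt, the residue count is n/3 − 1 with a complete stop
(TAA/TAG/AGA/AGG) and ⌊n/3⌋ with an incomplete, polyadenylation-completed
stop (T-- / TA-). The intergenic spacer before feature *i* is
start(i) − end(i−1) − 1, signed (negative = overlap), computed circularly
for the first feature.

**Composition.** On one strand, GC skew = (G − C)/(G + C) and AT skew =
(A − T)/(A + T); GC1/GC2/GC3 are the G+C percentages at each codon position
of a coding-gene set, and coding GC the overall fraction. Correspondence
analysis of a species × category count table is the SVD of the
chi-square-standardized residual matrix; total inertia equals χ²/n. Spearman
rank correlations use an exact permutation p-value for n ≤ 8.

**Heteroplasmy calling.** From samtools-mpileup text, after gating reads at
mapping and base quality ≥ 30, a site is a variant when coverage ≥ 20×,
exactly one alternative nucleotide is present, and it is supported by ≥ 2
reads with at least one on each strand, counting only support far from the
read ends and on reads with error-free flanks. Accepted calls are mapped
into codons — for an H-strand gene at position *p* in a gene starting at
*s*, gene position is p − s + 1 and the codon index ⌈(p − s + 1)/3⌉; L-strand
genes read the complement — and classified as synonymous, non-synonymous or
nonsense under the vertebrate mitochondrial code (ATA=Met, TGA=Trp,
AGA/AGG=stop).

**Simulation.** Synthetic circular genomes with configurable composition,
H/L gene layouts, stop-free CDS, a control region with an internal tandem
duplication, and single-end reads with planted heteroplasmies and a
positional error model, serialized in the exact pileup dialect the caller
parses.

## Worked example

The bundled reference annotation (`mitoasym.refdata`) drives the numbered
scripts under `analysis/`. Running `python analysis/01_annotation_stats.py`
prints:

```
genome: 17271 bp; features: 38 ({'tRNA': 22, 'rRNA': 2, 'CDS': 13, 'CR': 1})
control region: 1349 bp; shortest tRNA: 57 bp (the D-armless tRNA-Cys)
lengths + signed gaps telescope to 17271 bp
mismatches against the published derived columns: 0
```

i.e. every derived column of the published organization table (sizes,
residue counts, signed spacers such as the −10 bp ATPase8/6 overlap) is
recomputed exactly from coordinates and stop classes.
`python analysis/02_variant_effects.py` re-annotates the published
heteroplasmy table:

```
8/10 sites re-derive exactly as printed
  position 5690 (COI): single-base change implies ATA, not the printed AAA (re-derived effect non-synonymous, printed non-synonymous)
  position 12764 (ND5): single-base change implies GTC, not the printed GCT (re-derived effect non-synonymous, printed synonymous)
variant calls per sibling: {'AUS4': 5, 'AUS5': 7} (12 sample-site pairs)
shared sites: [6245, 15735]; minimum allele fraction at the deep Cytb site: 0.283
```

so position 15735 (Cytb codon 368, TTT→CTT, Phe→Leu) is heteroplasmic in all
three siblings including the reference individual, never below 28 % of
reads, while two printed rows are flagged as internally inconsistent with
their own gene frames rather than silently trusted.
`analysis/03_composition_ca.py` and `analysis/04_recovery.py` run the
composition/CA stage on synthetic genomes (axis 1 of the ordination ranks
six synthetic species exactly by GC content, Spearman ρ = 1.00) and measure
caller sensitivity: 100 % at 30 % heteroplasmy under 100× coverage, zero
false positives, collapsing to zero when fewer than two supporting reads are
expected.

There is also a CLI (`mitoasym annotate-stats | composition | ca | call |
simulate | run`) for running the same stages on files.

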