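# Methods

## Coordinates and the genetic code

All annotations are 1-based, fully closed intervals on the heavy (H) strand,
the convention of printed mitogenome organization tables; any half-open
arithmetic is internal. A feature crossing the replication origin is stored
with `end > genome length` and normalized modulo the circle on access.
L-strand features are annotated by their H-strand footprint; their coding
sequence is the reverse complement of that footprint, so the coding-frame
mapping of a genome position is `gene_pos = pos − start + 1` on H and
`end − pos + 1` on L, with `codon = ⌈gene_pos/3⌉` and offset
`((gene_pos − 1) mod 3) + 1`.

The genetic code defaults to the vertebrate mitochondrial code (NCBI
translation table 2: ATA→Met, TGA→Trp, AGA/AGG→stop), hardcoded as the
canonical 64-letter amino-acid string rather than taken from Biopython so
that Biopython's tables remain an independent oracle in the tests. Any codon
containing a non-ACGT base translates to `X` and is excluded from
composition counts. Terminal stops are excluded from translations; internal
stops are reported in place as `*`, never dropped.

## Annotation arithmetic

Residue counts follow from nucleotide length and stop class: `n/3 − 1` for a
complete stop, `⌊n/3⌋` for an incomplete stop (T-- / TA-), which is
completed to TAA by transcript polyadenylation. The intergenic spacer is
attributed to the *downstream* feature (`start(i) − end(i−1) − 1`, the first
feature closing the circle); this is the convention that reproduces the
reference table, and overlaps are reported as negative spacers, never
clipped. Because the sum of lengths and signed spacers telescopes, it equals
the genome length for any start-sorted circular annotation — a property the
tests fuzz. The tRNA-length z-score uses the population standard deviation
(`ddof=0`) by default since the source convention is unstated; `ddof=1` is a
parameter. The reference set behind the published z = −5.74 for the
D-armless tRNA-Cys is not distributed with the package; the operation takes
the reference lengths as input.

## Composition statistics

Skews are `(G − C)/(G + C)` and `(A − T)/(A + T)` on the analyzed strand —
the sign convention as printed in the source table; part of the literature
uses the opposite sign. N bases are excluded from all denominators; a skew
with a zero denominator is NaN with an explicit flag. GC1/GC2/GC3 are
computed on the concatenated, unaligned coding sequences (incomplete
trailing stop bases always trimmed, complete stop codons excluded by
default); alignment-column profiling would differ only through gap columns
and is not the default. GCp values are reported in percent and coding GC as
a fraction, deliberately mirroring the mixed units of the reference table.

Correspondence analysis is implemented directly (no installed package
exposes plain CA): with correspondence matrix `P = N/n`, row/column masses
`r, c`, the standardized residuals `S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` are
factorized by SVD and principal coordinates are `D_r^{-1/2}UΣ` /
`D_c^{-1/2}VΣ`; the trivial dimension is removed by centering. Correctness
is pinned by the χ²/n identity (cross-checked against
`scipy.stats.chi2_contingency`), the closed-form 2×2 case, and exact
reconstruction of `S` from the coordinates. Spearman correlations use
midranks for ties and, for n ≤ 8, an exact two-sided permutation p-value by
full enumeration; beyond that scipy's asymptotic value.

## The heteroplasmy filter cascade

Observations are first gated at base quality ≥ 30 and mapping quality ≥ 30
(coverage below always means gated depth; unknown mapping quality passes, on
the assumption of an upstream `-q`-filtered alignment). A site is then a
variant only if: gated coverage ≥ 20; exactly one distinct alternative
nucleotide among gated observations (a second alternative of any support
rejects the column as multiallelic); alternative support ≥ 2 reads with at
least one per strand; and the support survives two locality filters.

The source criteria "far away from the read ends" and "neighborhood
positions were error-free" are qualitative; here they are quantified as
defaults of ≥ 5 bp from both read ends and a ±5 bp reference-matching window
on supporting reads, both configurable. Crucially, these two filters remove
individual observations/reads from the support set rather than vetoing the
site: with ~30 supporting reads at a real heteroplasmy, the probability that
*all* of them sit ≥ 5 bp from the ends of a 66-bp read is ≈ 0.85³⁰ ≈ 0.7 %,
so a site-level veto would destroy sensitivity; acceptance instead requires
the *filtered* support to still meet the count and strand rules. Reported
alt/total counts (and hence allele fractions) are the quality-gated counts,
so a deeply covered site reads e.g. 44/93 regardless of how many supporting
observations the locality filters trimmed.

Raising the count-type thresholds (coverage, alt reads, end distance,
window) can only shrink the accepted set, and the tests verify this
exhaustively against a brute-force restatement of the criteria. The quality
gates are intentionally *not* monotone: a stricter base-quality gate can
remove a competing low-quality alternative base and thereby turn a
multiallelic rejection into an accept — a direct consequence of the
single-alternative criterion, not a defect. Indels are parsed but excluded
from calling; substitutions only. In cross-sample reports, a site carried by
the reference individual itself is surfaced through a reference-heteroplasmy
flag and excluded from its per-sample variant count, while still listed with
its support in every sample.

## The synthetic generator

`generate_genome` draws intergenic and structural-RNA sequence i.i.d. from
target base fractions (defaults match the strongly asymmetric H-strand
composition of an annual-killifish mitogenome: A .284, C .222, G .146,
T .348), builds CDS as start codon + stop-free codons + the specified stop
class, writes L-strand genes as reverse complements, and gives the control
region an internal tandem duplication (180 bp by default, the size reported
for the reference control region). Layouts may copy a real annotation
table verbatim, including overlaps; in an overlap the downstream feature's
sequence wins, so the stop-free CDS guarantee is unconditional only for
non-overlapping layouts (the toy default). Features may wrap the origin.

`simulate_pileup` places 66-bp single-end reads uniformly on the circle with
wrap-around and a 50/50 strand choice. Each read covering a planted site
carries the alternative base independently with the planted frequency.
Miscalls occur at a flat per-base rate (default 0.1 %) multiplied by 8 over
the last 5 sequenced bases of each read — the 3′-end degradation that the
read-end filter is built to absorb. Base-call qualities are informative of
error status: correct bases carry Q37 while miscalls draw from N(18, 5)
truncated to [2, 40]. This mirrors the strong association between low
quality and error in real base callers and is what makes a Q30-gated
analysis nearly error-free downstream of the gate — the regime the Q30
thresholds of the emulated pipeline were chosen for. It also bounds what
passing recovery tests show: they demonstrate the cascade's behaviour when
quality scores are well calibrated, not robustness to high-quality
systematic errors (reference bias, alignment artifacts), which real data
contain and this generator does not model. Tests that target the end and
neighborhood filters therefore raise the error quality explicitly.

Recovery experiments regenerate a ~4.5-kb toy genome, plant 10
well-separated sites (≥ 25 bp apart, so neighborhood windows never overlap a
second true site), and sweep frequency × coverage; a typical cell is
coverage 100× at frequency 0.30, where the cascade recovers ≥ 9/10 sites
with zero false positives per replicate, and sensitivity collapses to zero
once the expected alternative support falls below the two-read minimum.
Problem sizes throughout the tests and drivers (4.5–17 kb genomes, ≤ 100×
coverage, ≤ 20 replicates) were chosen as the smallest at which the binomial
expectations underlying each claim are comfortably resolved.

## Numerical and interface choices

- Deterministic everywhere: every stochastic component takes an explicit
  seed, and identical seeds give byte-identical pileup text and reports.
- The pileup parser implements the full samtools text dialect (`^` mapq,
  `$`, case-encoded strand, `*`/`#` deletions, `±n` indels, `><` skips) and
  tracks reads across columns (continuing reads precede newly started ones,
  as in position-sorted input), which propagates `^` mapping qualities and
  yields read identities for the neighborhood filter. Distances to read
  ends exist only in an extended three-column dialect (mapping qualities,
  read positions, read lengths); in the plain dialect they are unknown and
  the end filter passes, which is documented behaviour, not silent loss.
- Rejections are values with machine-readable reason codes
  (`min_coverage`, `multiallelic`, `strand_requirement`, …), so filter
  attrition is auditable.
- The bundled reference tables contain the published coordinates, codons
  and read counts only — not the genome sequence, which stays in GenBank.
  Whole-sequence quantities (the published base fractions and skews of the
  real genome) therefore cannot be recomputed offline here; the formula
  layer is instead pinned by hand-computable micro-sequences and
  reverse-complement symmetry properties, and two printed variant rows that
  contradict their own gene frames are flagged rather than asserted.

## Known limitations

De-novo annotation, read mapping, BAM input, indel calling and
mutation-rate estimation are out of scope. The error model is i.i.d. given
read position; no quality recalibration, duplicated-read structure or
realistic Illumina error spectra. Correspondence analysis assumes a strictly
positive margin (all-zero rows/columns are errors by contract). The
generator's composition targets are i.i.d. draws, so codon-structure
constraints (start/stop codons) perturb realized CDS composition slightly at
short lengths.
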