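"""Synthetic circular mitogenomes and heteroplasmic read pileups.

The generator provides ground-truth-known inputs for every other stage: a
toy circular genome with H/L-strand genes, configurable base composition, a
control region carrying an internal tandem duplication, and single-end reads
(the sequencing mode emulated is a 66-cycle single-end run, at toy scale)
with planted heteroplasmic variants and a positional error model.

Base-call qualities are informative of error status: correct bases carry a
constant high quality while miscalls draw a low quality (truncated normal,
mean ~Q18). This mirrors the strong association between low quality scores
and sequencing error that makes a Q30 gate effective in real pipelines; it
also means a Q30-gated analysis of defaults sees an essentially error-free
pileup, with raw errors exercising the quality gate rather than the
downstream filters. Tests that target the end-distance and neighborhood
filters raise the error quality explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hetcall import (
    CallerParams,
    FORWARD,
    REVERSE,
    PileupColumn,
    ReadObservation,
    call_pileup,
)
from .model import (
    BASES,
    CircularMitogenome,
    GeneAnnotation,
    GeneticCode,
    VERTEBRATE_MITO_CODE,
    reverse_complement,
)

__all__ = [
    "FeatureSpec",
    "GenomeSpec",
    "PlantedVariant",
    "ReadSimSpec",
    "generate_genome",
    "toy_genome_spec",
    "table2_layout",
    "simulate_pileup",
    "SimulatedSample",
    "format_pileup",
    "simulate_siblings",
    "recovery_experiment",
    "plant_random_variants",
]

_BASE2I = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class FeatureSpec:
    """One feature of a synthetic genome layout.

    ``gap_before`` is the signed spacer to the previous feature's end
    (negative = overlap); ``stop_class`` is a complete stop codon (TAA/TAG),
    an incomplete one (T--/TA-) or None for non-CDS features.
    """

    name: str
    feature_type: str
    length: int
    strand: str = "H"
    start_codon: str = "ATG"
    stop_class: str | None = None
    gap_before: int = 0


@dataclass(frozen=True)
class GenomeSpec:
    """Layout plus composition targets for a synthetic circular mitogenome."""

    layout: tuple[FeatureSpec, ...]
    base_fractions: tuple[float, float, float, float] = (0.284, 0.222, 0.146, 0.348)
    length: int | None = None  # None: ends exactly at the last feature
    cr_duplication_length: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_fractions) - 1.0) > 1e-9:
            raise ValueError("base fractions must sum to 1")
        if not self.layout:
            raise ValueError("empty layout")


def _coordinates(spec: GenomeSpec) -> tuple[list[tuple[FeatureSpec, int, int]], int]:
    placed = []
    prev_end = 0
    for fs in spec.layout:
        start = prev_end + fs.gap_before + 1
        if start < 1:
            raise ValueError(f"{fs.name}: layout places start before position 1")
        end = start + fs.length - 1
        placed.append((fs, start, end))
        prev_end = end
    length = spec.length if spec.length is not None else prev_end
    if prev_end > length:
        # last feature(s) wrap across the origin; keep end > length
        if prev_end - length >= placed[0][1]:
            raise ValueError("infeasible layout: wrap-around collides with the first feature")
    return placed, length


def _random_bases(rng: np.random.Generator, n: int, fractions) -> np.ndarray:
    return rng.choice(4, size=n, p=list(fractions)).astype(np.int8)


def _random_cds(rng: np.random.Generator, fs: FeatureSpec, fractions,
                code: GeneticCode) -> str:
    stop_class = fs.stop_class or "TAA"
    if stop_class in ("TAA", "TAG", "AGA", "AGG"):
        suffix, expected_mod = stop_class, 0
    elif stop_class == "T--":
        suffix, expected_mod = "T", 1
    elif stop_class == "TA-":
        suffix, expected_mod = "TA", 2
    else:
        raise ValueError(f"{fs.name}: unknown stop class {stop_class!r}")
    if fs.length % 3 != expected_mod:
        raise ValueError(
            f"{fs.name}: length {fs.length} incompatible with stop class {stop_class}"
        )
    n_internal = (fs.length - 3 - len(suffix)) // 3
    if n_internal < 0:
        raise ValueError(f"{fs.name}: CDS too short")
    codons = []
    while len(codons) < n_internal:
        draw = _random_bases(rng, 3, fractions)
        codon = "".join(BASES[i] for i in draw)
        if not code.is_stop(codon):
            codons.append(codon)
    return fs.start_codon + "".join(codons) + suffix


def _random_cr(rng: np.random.Generator, length: int, dup_len: int, fractions) -> str:
    if dup_len >= length:
        raise ValueError("duplication must be shorter than the control region")
    core = "".join(BASES[i] for i in _random_bases(rng, length - dup_len, fractions))
    if dup_len == 0:
        return core
    a = (len(core) - dup_len) // 2
    dup = core[a : a + dup_len]
    return core[: a + dup_len] + dup + core[a + dup_len :]


def generate_genome(
    spec: GenomeSpec, code: GeneticCode = VERTEBRATE_MITO_CODE
) -> tuple[CircularMitogenome, dict]:
    """Generate a synthetic circular mitogenome from a layout spec.

    CDS features begin with their start codon, are internally stop-free under
    ``code`` and end per their stop class; intergenic and structural-RNA
    sequence is drawn i.i.d. from the target composition; the CR feature
    carries an internal tandem duplication. Deterministic for a fixed seed.

    Where the layout makes features overlap, the later (downstream) feature's
    sequence wins in the overlap, so the stop-free guarantee holds
    unconditionally only for non-overlapping layouts.
    """
    rng = np.random.default_rng(spec.seed)
    placed, length = _coordinates(spec)
    buf = list("".join(BASES[i] for i in _random_bases(rng, length, spec.base_fractions)))
    annotations = []
    for fs, start, end in placed:
        if fs.feature_type == "CDS":
            coding = _random_cds(rng, fs, spec.base_fractions, code)
            written = coding if fs.strand == "H" else reverse_complement(coding)
        elif fs.feature_type == "CR":
            written = _random_cr(rng, fs.length, spec.cr_duplication_length,
                                 spec.base_fractions)
        else:
            written = None  # keep the background draw
        if written is not None:
            for k, ch in enumerate(written):
                buf[(start - 1 + k) % length] = ch
        annotations.append(GeneAnnotation(
            name=fs.name, start=start, end=end, strand=fs.strand,
            feature_type=fs.feature_type,
            start_codon=fs.start_codon if fs.feature_type == "CDS" else None,
            stop_codon=fs.stop_class if fs.feature_type == "CDS" else None,
        ))
    genome = CircularMitogenome(sequence="".join(buf), annotations=annotations,
                                name=f"synthetic-{spec.seed}")
    truth = {
        "seed": spec.seed,
        "length": length,
        "coordinates": [(fs.name, s, e, fs.strand) for fs, s, e in placed],
    }
    return genome, truth


def toy_genome_spec(seed: int = 0, **overrides) -> GenomeSpec:
    """Default toy mitogenome: ~4.5 kb, H/L CDS mix, duplicated CR.

    Base fractions default to the strongly asymmetric composition typical of
    an annual-killifish H strand (A .284, C .222, G .146, T .348).
    """
    layout = (
        FeatureSpec("tRNA-Phe", "tRNA", 69),
        FeatureSpec("rRNA-S", "rRNA", 400),
        FeatureSpec("GENE1", "CDS", 975, "H", "ATG", "TAA"),
        FeatureSpec("tRNA-X", "tRNA", 70, "L"),
        FeatureSpec("GENE2", "CDS", 1045, "H", "ATG", "T--"),
        FeatureSpec("GENE3", "CDS", 683, "H", "ATG", "TA-"),
        FeatureSpec("GENE4", "CDS", 522, "L", "ATG", "TAG"),
        FeatureSpec("tRNA-Y", "tRNA", 68),
        FeatureSpec("CR", "CR", 700),
    )
    return GenomeSpec(layout=layout, cr_duplication_length=180, seed=seed, **overrides)


def table2_layout(annotations: Sequence[GeneAnnotation]) -> tuple[FeatureSpec, ...]:
    """Convert a real annotation table into a synthetic layout.

    Keeps every coordinate (including overlaps) so a genome generated from it
    reproduces the original table's derived columns exactly.
    """
    specs = []
    prev_end = 0
    for a in sorted(annotations, key=lambda x: x.start):
        specs.append(FeatureSpec(
            name=a.name, feature_type=a.feature_type, length=a.length_nt,
            strand=a.strand, start_codon=a.start_codon or "ATG",
            stop_class=a.stop_codon, gap_before=a.start - prev_end - 1,
        ))
        prev_end = a.end
    return tuple(specs)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedVariant:
    position: int  # 1-based
    alt: str
    frequency: float

    def __post_init__(self) -> None:
        if not (0 < self.frequency < 1):
            raise ValueError("heteroplasmy frequency must be in (0, 1)")


@dataclass(frozen=True)
class ReadSimSpec:
    """Single-end read simulation parameters.

    ``error_rate`` is the flat per-base miscall rate; within the last
    ``end_error_length`` sequenced bases of each read it is multiplied by
    ``end_error_multiplier`` (3'-end degradation, exercising the read-end
    filter). Correct bases carry ``base_quality``; miscalls draw their
    quality from N(error_quality_mean, error_quality_sd) truncated to
    [2, 40].
    """

    coverage: float
    read_length: int = 66
    error_rate: float = 0.001
    end_error_multiplier: float = 8.0
    end_error_length: int = 5
    variants: tuple[PlantedVariant, ...] = ()
    base_quality: int = 37
    error_quality_mean: float = 18.0
    error_quality_sd: float = 5.0
    mapping_quality: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")


@dataclass
class SimulatedSample:
    columns: list[PileupColumn]
    truth: pd.DataFrame  # one row per planted site
    n_reads: int
    spec: ReadSimSpec

    def text(self, chrom: str = "mt") -> str:
        return format_pileup(self.columns, chrom=chrom)


def simulate_pileup(genome: CircularMitogenome, spec: ReadSimSpec) -> SimulatedSample:
    """Simulate a single sample's pileup over the whole circle.

    Reads are placed uniformly on the circle with wrap-around and a 50/50
    strand choice; each read covering a planted site carries the alternative
    base independently with the planted frequency; miscalls follow the
    positional error model. The truth table records, per planted site, the
    realized alternative-read count and coverage.
    """
    L = genome.length
    rl = spec.read_length
    for v in spec.variants:
        if not (1 <= v.position <= L):
            raise ValueError(f"planted position {v.position} outside genome")
    rng = np.random.default_rng(spec.seed)
    n_reads = max(1, int(round(spec.coverage * L / rl)))
    starts = rng.integers(0, L, size=n_reads)
    is_rev = rng.random(n_reads) < 0.5
    offsets = np.arange(rl)
    pos = (starts[:, None] + offsets[None, :]) % L  # genome coordinates, 0-based
    gidx = np.fromiter((_BASE2I.get(b, 0) for b in genome.sequence), dtype=np.int8, count=L)
    base = gidx[pos].astype(np.int8)
    readpos = np.where(is_rev[:, None], rl - offsets[None, :], offsets[None, :] + 1)

    # plant heteroplasmic variants (per-read Bernoulli at the planted frequency)
    truth_rows = []
    for v in spec.variants:
        site0 = v.position - 1
        off = (site0 - starts) % L
        covered = off < rl
        carrier = covered & (rng.random(n_reads) < v.frequency)
        rows = np.flatnonzero(carrier)
        base[rows, off[rows]] = _BASE2I[v.alt.upper()]
        truth_rows.append({
            "position": v.position,
            "ref": genome.sequence[site0],
            "alt": v.alt.upper(),
            "frequency": v.frequency,
            "coverage": int(covered.sum()),
            "alt_reads_planted": int(carrier.sum()),
        })

    # positional error model
    in_end = readpos > rl - spec.end_error_length
    rate = np.where(in_end, spec.error_rate * spec.end_error_multiplier, spec.error_rate)
    err = rng.random((n_reads, rl)) < rate
    n_err = int(err.sum())
    if n_err:
        base[err] = (base[err] + rng.integers(1, 4, size=n_err)) % 4
    qual = np.full((n_reads, rl), spec.base_quality, dtype=np.int16)
    if n_err:
        eq = np.rint(rng.normal(spec.error_quality_mean, spec.error_quality_sd, size=n_err))
        qual[err] = np.clip(eq, 2, 40).astype(np.int16)

    # realized alt support after errors (errors can create or destroy support)
    for row, v in zip(truth_rows, spec.variants):
        site0 = v.position - 1
        off = (site0 - starts) % L
        covered = off < rl
        rows = np.flatnonzero(covered)
        row["alt_reads"] = int((base[rows, off[rows]] == _BASE2I[v.alt.upper()]).sum())
    truth = pd.DataFrame(
        truth_rows,
        columns=["position", "ref", "alt", "frequency", "coverage",
                 "alt_reads_planted", "alt_reads"],
    )

    # assemble per-position columns, reads ordered by start within a column
    flat_pos = pos.ravel()
    order = np.lexsort((np.repeat(starts, rl), flat_pos))
    flat_pos = flat_pos[order]
    flat_base = base.ravel()[order]
    flat_qual = qual.ravel()[order]
    flat_readpos = readpos.ravel()[order]
    flat_read = np.repeat(np.arange(n_reads), rl)[order]
    flat_rev = np.repeat(is_rev, rl)[order]

    columns: list[PileupColumn] = []
    boundaries = np.flatnonzero(np.diff(flat_pos)) + 1
    starts_idx = np.concatenate(([0], boundaries))
    ends_idx = np.concatenate((boundaries, [flat_pos.size]))
    seq = genome.sequence
    for a, b in zip(starts_idx, ends_idx):
        p0 = int(flat_pos[a])
        obs = []
        for k in range(a, b):
            rp = int(flat_readpos[k])
            obs.append(ReadObservation(
                base=BASES[flat_base[k]],
                strand=REVERSE if flat_rev[k] else FORWARD,
                base_quality=int(flat_qual[k]),
                mapping_quality=spec.mapping_quality,
                dist_to_5prime=rp - 1,
                dist_to_3prime=rl - rp,
                read_id=int(flat_read[k]),
            ))
        columns.append(PileupColumn(position=p0 + 1, ref_base=seq[p0], observations=obs))
    return SimulatedSample(columns=columns, truth=truth, n_reads=n_reads, spec=spec)


def format_pileup(columns: Sequence[PileupColumn], chrom: str = "mt",
                  extended: bool = True) -> str:
    """Serialize pileup columns to samtools-mpileup text.

    With ``extended`` three extra columns are written: per-observation
    mapping qualities (Phred+33), read positions (1-based, in sequencing
    orientation) and read lengths — the dialect from which the parser can
    reconstruct distances to read ends.
    """
    lines = []
    for col in columns:
        parts = []
        quals = []
        mapqs = []
        rposs = []
        rlens = []
        for o in col.observations:
            rp = None if o.dist_to_5prime is None else o.dist_to_5prime + 1
            rlen = (
                None
                if o.dist_to_5prime is None or o.dist_to_3prime is None
                else o.dist_to_5prime + o.dist_to_3prime + 1
            )
            # leftmost/rightmost genome offset of the read at this column
            left = (o.dist_to_5prime if o.strand == FORWARD else o.dist_to_3prime)
            right = (o.dist_to_3prime if o.strand == FORWARD else o.dist_to_5prime)
            s = ""
            if left == 0:
                mq = o.mapping_quality if o.mapping_quality is not None else 255
                s += "^" + chr(min(mq, 93) + 33)
            if o.is_deletion:
                s += "*" if o.strand == FORWARD else "#"
            elif o.base == col.ref_base:
                s += "." if o.strand == FORWARD else ","
            else:
                s += o.base.upper() if o.strand == FORWARD else o.base.lower()
            if right == 0:
                s += "$"
            parts.append(s)
            quals.append(chr(min(o.base_quality, 93) + 33))
            mapqs.append(chr(min(o.mapping_quality if o.mapping_quality is not None else 255, 93) + 33))
            rposs.append(str(rp) if rp is not None else "0")
            rlens.append(str(rlen) if rlen is not None else "0")
        fields = [chrom, str(col.position), col.ref_base, str(len(col.observations)),
                  "".join(parts), "".join(quals)]
        if extended:
            fields += ["".join(mapqs), ",".join(rposs), ",".join(rlens)]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def simulate_siblings(
    genome: CircularMitogenome,
    maternal_plan: Sequence[PlantedVariant],
    samples: Sequence[str],
    coverage: float = 100.0,
    frequency_jitter: float = 0.3,
    seed: int = 0,
    **spec_overrides,
) -> dict[str, SimulatedSample]:
    """Simulate full siblings sharing a maternal heteroplasmy plan.

    Each sibling inherits every planted site with its frequency perturbed by
    a lognormal factor (sd ``frequency_jitter``), emulating bottleneck-driven
    frequency drift among siblings.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i, sample in enumerate(samples):
        variants = []
        for v in maternal_plan:
            f = float(np.clip(v.frequency * rng.lognormal(0.0, frequency_jitter), 0.01, 0.95))
            variants.append(PlantedVariant(v.position, v.alt, f))
        spec = ReadSimSpec(coverage=coverage, variants=tuple(variants),
                           seed=int(rng.integers(0, 2**31 - 1)), **spec_overrides)
        out[sample] = simulate_pileup(genome, spec)
    return out


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def plant_random_variants(
    genome: CircularMitogenome,
    n_sites: int,
    frequency: float,
    rng: np.random.Generator,
    min_spacing: int = 25,
) -> tuple[PlantedVariant, ...]:
    """Choose well-separated random sites and non-reference alt bases."""
    L = genome.length
    for _ in range(1000):
        sites = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1
        gaps = np.diff(np.concatenate((sites, [sites[0] + L])))
        if (gaps >= min_spacing).all():
            break
    else:
        raise ValueError("could not place variants with the requested spacing")
    variants = []
    for s in sites:
        ref = genome.sequence[s - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        variants.append(PlantedVariant(int(s), str(alt), frequency))
    return tuple(variants)


def recovery_experiment(
    frequencies: Sequence[float],
    coverages: Sequence[float],
    replicates: int,
    seed: int = 0,
    genome: CircularMitogenome | None = None,
    n_sites: int = 10,
    params: CallerParams = CallerParams(),
    **spec_overrides,
) -> pd.DataFrame:
    """Detection-rate table over a frequency x coverage grid.

    Per cell and replicate: sensitivity (planted sites recovered at their
    planted alt allele), count of false-positive sites, and mean absolute
    allele-fraction error over recovered sites. Reproducible under ``seed``.
    """
    if not list(frequencies) or not list(coverages):
        raise ValueError("empty grid")
    if genome is None:
        genome, _ = generate_genome(toy_genome_spec(seed=seed))
    rng = np.random.default_rng(seed)
    rows = []
    for freq in frequencies:
        for cov in coverages:
            for rep in range(replicates):
                variants = plant_random_variants(genome, n_sites, freq, rng)
                spec = ReadSimSpec(coverage=cov, variants=variants,
                                   seed=int(rng.integers(0, 2**31 - 1)),
                                   **spec_overrides)
                sample = simulate_pileup(genome, spec)
                accepted, _ = call_pileup(sample.columns, params)
                planted = {(v.position, v.alt) for v in variants}
                hits = [c for c in accepted if (c.position, c.alt_base) in planted]
                false = [c for c in accepted if (c.position, c.alt_base) not in planted]
                af_err = (
                    float(np.mean([abs(c.allele_fraction - freq) for c in hits]))
                    if hits else float("nan")
                )
                rows.append({
                    "frequency": freq, "coverage": cov, "replicate": rep,
                    "sensitivity": len(hits) / n_sites,
                    "false_positives": len(false),
                    "mean_af_error": af_err,
                })
    return pd.DataFrame(rows)
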