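"""Pileup-based heteroplasmy caller with codon-level effect annotation.

A site is reported as a (heteroplasmic) variant only when, among
quality-gated read observations, ALL of the following hold:

i.   coverage is at least ``min_coverage`` (coverage = gated depth);
ii.  there is exactly one distinct alternative nucleotide;
iii. the alternative is supported by at least ``min_alt_reads`` reads with at
     least one on each DNA strand — guarding against strand-specific
     sequencing artifacts and read duplicates;
iv.  enough of that support sits far from the read ends and on reads whose
     flanking positions match the reference (error-free neighborhood).

Criteria iii/iv act on *filtered* support: observations close to a read end
or on locally noisy reads are removed from the support set rather than
vetoing the whole site, and acceptance requires the filtered support to
still satisfy the count and strand rules. Reported alt/total counts are the
quality-gated counts, so the allele fraction is gated-alt / gated-depth.

Rejections are values, not errors, and carry machine-readable reason codes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .model import (
    CircularMitogenome,
    GeneticCode,
    VERTEBRATE_MITO_CODE,
    extract_gene_sequence,
    position_to_codon,
)

__all__ = [
    "ReadObservation",
    "PileupColumn",
    "CallerParams",
    "CandidateCall",
    "Rejection",
    "VariantCall",
    "parse_pileup",
    "gate_observations",
    "call_column",
    "call_pileup",
    "transition_or_transversion",
    "classify_effect",
    "annotate_call",
    "cross_sample_report",
    "CrossSampleReport",
]

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# reason codes, in the order the criteria are checked
REASON_MIN_COVERAGE = "min_coverage"
REASON_NO_ALT = "no_alt"
REASON_MULTIALLELIC = "multiallelic"
REASON_MIN_ALT_READS = "min_alt_reads"
REASON_READ_END = "read_end_distance"
REASON_NEIGHBORHOOD = "neighborhood"
REASON_STRAND = "strand_requirement"


@dataclass
class ReadObservation:
    """One read's observation at one genome position (forward-strand base)."""

    base: str
    strand: str  # forward | reverse (mapping strand)
    base_quality: int
    mapping_quality: int | None = None  # None = unknown (pre-gated upstream)
    dist_to_5prime: int | None = None  # bp within the read as sequenced
    dist_to_3prime: int | None = None
    read_id: object = None
    is_deletion: bool = False
    has_indel: bool = False  # an indel follows this base in the read


@dataclass
class PileupColumn:
    position: int  # 1-based mitogenome coordinate
    ref_base: str
    observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the variant filter cascade.

    ``min_read_end_distance`` and ``neighborhood_window`` quantify the
    qualitative requirements that alternative bases lie far from read ends
    and on locally error-free reads; both are assumptions of this
    implementation and configurable.
    """

    min_coverage: int = 20
    min_alt_reads: int = 2
    require_both_strands: bool = True
    min_base_quality: int = 30
    min_mapping_quality: int = 30
    min_read_end_distance: int = 5
    neighborhood_window: int = 5
    max_alt_alleles: int = 1

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_alt_reads", "min_base_quality",
                     "min_mapping_quality", "min_read_end_distance", "neighborhood_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_alt_alleles != 1:
            raise ValueError("the caller is defined for exactly one alternative allele")


@dataclass
class CandidateCall:
    position: int
    ref_base: str
    alt_base: str
    alt_reads: int  # quality-gated alt observations
    total_reads: int  # quality-gated depth
    alt_forward: int
    alt_reverse: int
    filtered_support: int  # support surviving end-distance and neighborhood filters

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.total_reads


@dataclass
class Rejection:
    position: int
    reason: str
    detail: str = ""


@dataclass
class VariantCall:
    """An accepted site with codon-level annotation on the coding strand."""

    position: int
    gene: str | None
    ref_base: str
    alt_base: str
    alt_reads: int
    total_reads: int
    substitution_class: str  # Ts | Tv
    codon_index: int | None = None
    codon_offset: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    aa_change: str | None = None
    effect: str = "non-coding"

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.total_reads


# ---------------------------------------------------------------------------
# Pileup parsing (samtools mpileup text dialect)
# ---------------------------------------------------------------------------


class PileupParseError(ValueError):
    pass


def _open_lines(source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source
    elif isinstance(source, (list, tuple)):
        yield from source
    elif isinstance(source, str) and "\n" in source:
        yield from io.StringIO(source)
    else:
        with open(source) as fh:
            yield from fh


def parse_pileup(source) -> list[PileupColumn]:
    """Parse samtools-mpileup text into pileup columns.

    Standard columns are ``chrom pos ref depth bases quals``. The base string
    is decoded in full: ``^`` + mapq char (read start), ``$`` (read end),
    case-encoded strand, ``*``/``#`` deletion placeholders, ``+n``/``-n``
    indel suffixes and ``><`` reference skips. Reads are tracked across
    columns (continuing reads precede newly started ones, as in
    position-sorted input), which propagates the ``^`` mapping quality and
    gives every observation a read id usable for neighborhood checks.

    Three optional extended columns may follow: per-observation mapping
    qualities (Phred+33 string, as samtools ``-s``), comma-separated 1-based
    positions of the base within the read as sequenced, and comma-separated
    read lengths. Without them, distances to the read ends are unknown
    (``None``) and mapping quality falls back to the ``^`` value.
    """
    columns: list[PileupColumn] = []
    active: list[dict] = []  # per still-open read: {"id", "mapq"}
    next_read_id = 0
    last_chrom = None
    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupParseError(f"line {lineno}: expected >= 6 columns, got {len(fields)}")
        chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
        if chrom != last_chrom:
            active = []
            last_chrom = chrom
        pos, depth = int(pos_s), int(depth_s)
        ref = ref.upper()

        # decode the base string
        decoded: list[dict] = []  # base, strand, starts, ends, mapq_start, deletion, indel
        i = 0
        n = len(bases)
        while i < n:
            c = bases[i]
            entry = {"starts": False, "ends": False, "mapq": None,
                     "deletion": False, "indel": False}
            if c == "^":
                if i + 2 > n:
                    raise PileupParseError(f"line {lineno}: dangling ^ marker")
                entry["starts"] = True
                entry["mapq"] = ord(bases[i + 1]) - 33
                i += 2
                c = bases[i]
            if c in ".,":
                entry["base"] = ref
                entry["strand"] = FORWARD if c == "." else REVERSE
            elif c in "><":
                entry["base"] = "N"
                entry["strand"] = FORWARD if c == ">" else REVERSE
                entry["deletion"] = True  # reference skip: no base observed
            elif c in "*#":
                entry["base"] = "N"
                entry["strand"] = FORWARD if c == "*" else REVERSE
                entry["deletion"] = True
            elif c.upper() in "ACGTN":
                entry["base"] = c.upper()
                entry["strand"] = FORWARD if c.isupper() else REVERSE
            else:
                raise PileupParseError(f"line {lineno}: unexpected character {c!r} in base string")
            i += 1
            # optional indel suffix
            if i < n and bases[i] in "+-":
                j = i + 1
                while j < n and bases[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError(f"line {lineno}: malformed indel")
                ilen = int(bases[i + 1 : j])
                i = j + ilen
                entry["indel"] = True
            if i < n and bases[i] == "$":
                entry["ends"] = True
                i += 1
            decoded.append(entry)

        if len(decoded) != depth or len(quals) != depth:
            raise PileupParseError(
                f"line {lineno}: depth {depth} does not match {len(decoded)} bases / "
                f"{len(quals)} qualities"
            )

        mapqs = readpos = readlens = None
        if len(fields) >= 7 and fields[6]:
            mapqs = [ord(ch) - 33 for ch in fields[6]]
            if len(mapqs) != depth:
                raise PileupParseError(f"line {lineno}: mapping-quality column length mismatch")
        if len(fields) >= 9 and fields[7] and fields[8]:
            readpos = [int(x) for x in fields[7].split(",")]
            readlens = [int(x) for x in fields[8].split(",")]
            if len(readpos) != depth or len(readlens) != depth:
                raise PileupParseError(f"line {lineno}: read-position column length mismatch")

        # map observations onto tracked reads: continuing first, new appended
        cont_iter = iter(active)
        new_active: list[dict] = []
        obs_list: list[ReadObservation] = []
        assigned: list[tuple[dict, dict]] = []
        for entry in decoded:
            if entry["starts"]:
                read = {"id": next_read_id, "mapq": entry["mapq"]}
                next_read_id += 1
            else:
                read = next(cont_iter, None)
                if read is None:  # untracked read (pileup did not begin at its start)
                    read = {"id": next_read_id, "mapq": None}
                    next_read_id += 1
            assigned.append((entry, read))
        for k, (entry, read) in enumerate(assigned):
            if not entry["ends"]:
                new_active.append(read)
            mq = mapqs[k] if mapqs is not None else read["mapq"]
            d5 = d3 = None
            if readpos is not None:
                d5 = readpos[k] - 1
                d3 = readlens[k] - readpos[k]
            obs_list.append(
                ReadObservation(
                    base=entry["base"],
                    strand=entry["strand"],
                    base_quality=ord(quals[k]) - 33,
                    mapping_quality=mq,
                    dist_to_5prime=d5,
                    dist_to_3prime=d3,
                    read_id=read["id"],
                    is_deletion=entry["deletion"],
                    has_indel=entry["indel"],
                )
            )
        active = new_active
        columns.append(PileupColumn(position=pos, ref_base=ref, observations=obs_list))
    return columns


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def gate_observations(obs: Iterable[ReadObservation], params: CallerParams) -> list[ReadObservation]:
    """Quality gate: base and mapping quality thresholds, deletions dropped.

    Unknown mapping quality passes (the upstream mapper is assumed to have
    gated already, mirroring a `-q`-filtered BAM).
    """
    out = []
    for o in obs:
        if o.is_deletion or o.base == "N":
            continue
        if o.base_quality < params.min_base_quality:
            continue
        if o.mapping_quality is not None and o.mapping_quality < params.min_mapping_quality:
            continue
        out.append(o)
    return out


def _far_from_ends(o: ReadObservation, min_dist: int) -> bool:
    if o.dist_to_5prime is None or o.dist_to_3prime is None:
        return True  # unknowable in the plain dialect; documented assumption
    return o.dist_to_5prime >= min_dist and o.dist_to_3prime >= min_dist


def _neighborhood_clean(
    o: ReadObservation,
    position: int,
    context: Mapping[int, PileupColumn] | None,
    window: int,
) -> bool:
    """Whether the supporting read matches the reference at flanking positions."""
    if context is None or o.read_id is None or window == 0:
        return True
    for q in range(position - window, position + window + 1):
        if q == position:
            continue
        col = context.get(q)
        if col is None:
            continue
        for other in col.observations:
            if other.read_id == o.read_id:
                if not other.is_deletion and other.base != col.ref_base:
                    return False
                break
    return True


def call_column(
    col: PileupColumn,
    params: CallerParams = CallerParams(),
    context: Mapping[int, PileupColumn] | None = None,
) -> CandidateCall | Rejection:
    """Apply the variant criteria to one pileup column.

    ``context`` (position -> column, e.g. built over the whole pileup) is
    needed for the error-free-neighborhood criterion; without it that check
    is skipped.
    """
    gated = gate_observations(col.observations, params)
    coverage = len(gated)
    if coverage < params.min_coverage:
        return Rejection(col.position, REASON_MIN_COVERAGE, f"gated depth {coverage}")
    alt_bases = sorted({o.base for o in gated if o.base != col.ref_base})
    if not alt_bases:
        return Rejection(col.position, REASON_NO_ALT, "")
    if len(alt_bases) > params.max_alt_alleles:
        return Rejection(col.position, REASON_MULTIALLELIC, ",".join(alt_bases))
    alt = alt_bases[0]
    support = [o for o in gated if o.base == alt]
    if len(support) < params.min_alt_reads:
        return Rejection(col.position, REASON_MIN_ALT_READS, f"{len(support)} alt reads")
    far = [o for o in support if _far_from_ends(o, params.min_read_end_distance)]
    if len(far) < params.min_alt_reads:
        return Rejection(col.position, REASON_READ_END,
                         f"{len(far)} alt reads far from read ends")
    clean = [o for o in far
             if _neighborhood_clean(o, col.position, context, params.neighborhood_window)]
    if len(clean) < params.min_alt_reads:
        return Rejection(col.position, REASON_NEIGHBORHOOD,
                         f"{len(clean)} alt reads with clean flanks")
    fwd = sum(1 for o in clean if o.strand == FORWARD)
    rev = len(clean) - fwd
    if params.require_both_strands and (fwd == 0 or rev == 0):
        return Rejection(col.position, REASON_STRAND, f"{fwd} forward / {rev} reverse")
    return CandidateCall(
        position=col.position,
        ref_base=col.ref_base,
        alt_base=alt,
        alt_reads=len(support),
        total_reads=coverage,
        alt_forward=sum(1 for o in support if o.strand == FORWARD),
        alt_reverse=sum(1 for o in support if o.strand == REVERSE),
        filtered_support=len(clean),
    )


def call_pileup(
    columns: Sequence[PileupColumn],
    params: CallerParams = CallerParams(),
) -> tuple[list[CandidateCall], list[Rejection]]:
    """Run the filter cascade over a whole pileup with neighborhood context."""
    context = {c.position: c for c in columns}
    accepted: list[CandidateCall] = []
    rejected: list[Rejection] = []
    for col in columns:
        res = call_column(col, params, context)
        if isinstance(res, CandidateCall):
            accepted.append(res)
        else:
            rejected.append(res)
    return accepted, rejected


# ---------------------------------------------------------------------------
# Effect annotation
# ---------------------------------------------------------------------------

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "STOP", "X": "Xaa",
}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def transition_or_transversion(ref: str, alt: str) -> str:
    pair = {ref.upper(), alt.upper()}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "Ts"
    return "Tv"


def classify_effect(ref_codon: str, alt_codon: str,
                    code: GeneticCode = VERTEBRATE_MITO_CODE) -> str:
    """synonymous / non-synonymous / nonsense for a codon substitution."""
    ref_aa = code.amino_acid(ref_codon)
    alt_aa = code.amino_acid(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    if alt_aa == ref_aa:
        return "synonymous"
    return "non-synonymous"


def annotate_call(
    call: CandidateCall,
    genome: CircularMitogenome,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> list[VariantCall]:
    """Codon-level annotation of an accepted call against the genome annotation.

    L-strand genes read the complement of both alleles; a position inside two
    overlapping CDS yields one annotated record per gene; a position outside
    any CDS is passed through as non-coding.
    """
    subst = transition_or_transversion(call.ref_base, call.alt_base)
    cds_hits = genome.features_at(call.position, feature_type="CDS")
    if not cds_hits:
        return [VariantCall(
            position=call.position, gene=None, ref_base=call.ref_base,
            alt_base=call.alt_base, alt_reads=call.alt_reads,
            total_reads=call.total_reads, substitution_class=subst,
        )]
    out = []
    for g in cds_hits:
        codon_index, offset = position_to_codon(g, call.position)
        gene_seq = extract_gene_sequence(genome, g)
        ref_codon = gene_seq[(codon_index - 1) * 3 : codon_index * 3]
        if len(ref_codon) < 3:  # incomplete terminal codon (T-- / TA- stops)
            out.append(VariantCall(
                position=call.position, gene=g.name, ref_base=call.ref_base,
                alt_base=call.alt_base, alt_reads=call.alt_reads,
                total_reads=call.total_reads, substitution_class=subst,
                codon_index=codon_index, codon_offset=offset,
                effect="incomplete-codon",
            ))
            continue
        alt_allele = call.alt_base if g.strand == "H" else _COMPLEMENT[call.alt_base]
        alt_codon = ref_codon[: offset - 1] + alt_allele + ref_codon[offset:]
        effect = classify_effect(ref_codon, alt_codon, code)
        aa_change = f"{AA3[code.amino_acid(ref_codon)]} to {AA3[code.amino_acid(alt_codon)]}"
        out.append(VariantCall(
            position=call.position, gene=g.name, ref_base=call.ref_base,
            alt_base=call.alt_base, alt_reads=call.alt_reads,
            total_reads=call.total_reads, substitution_class=subst,
            codon_index=codon_index, codon_offset=offset,
            ref_codon=ref_codon, alt_codon=alt_codon,
            aa_change=aa_change, effect=effect,
        ))
    return out


# ---------------------------------------------------------------------------
# Cross-sample reporting
# ---------------------------------------------------------------------------


@dataclass
class CrossSampleReport:
    """One row per variant site with per-sample support strings.

    ``variant_counts`` counts variant calls per non-reference sample; a site
    where the reference individual itself carries the alternative allele is
    flagged as reference heteroplasmy rather than counted as a call against
    self.
    """

    table: pd.DataFrame
    variant_counts: dict[str, int]
    reference_sample: str | None

    @property
    def n_sample_site_pairs(self) -> int:
        return sum(self.variant_counts.values())


def cross_sample_report(
    sample_calls: Mapping[str, Sequence[VariantCall]],
    reference_sample: str | None = None,
) -> CrossSampleReport:
    if not sample_calls:
        raise ValueError("need at least one sample")
    samples = list(sample_calls)
    sites: dict[int, dict] = {}
    for sample, calls in sample_calls.items():
        for v in calls:
            rec = sites.setdefault(v.position, {"call": v, "support": {}})
            prev = rec["call"]
            if prev.ref_base != v.ref_base:
                raise ValueError(
                    f"inconsistent reference allele at {v.position}: "
                    f"{prev.ref_base} vs {v.ref_base}"
                )
            rec["support"][sample] = (v.alt_reads, v.total_reads)
    rows = []
    counts = {s: 0 for s in samples if s != reference_sample}
    for position in sorted(sites):
        rec = sites[position]
        v: VariantCall = rec["call"]
        carriers = sorted(rec["support"])
        row = {
            "position": position,
            "gene": v.gene,
            "nucleotide_change": f"{v.ref_base} to {v.alt_base}",
            "ts_tv": v.substitution_class,
            "codon_index": v.codon_index,
            "codon_change": (
                f"{v.ref_codon} to {v.alt_codon}" if v.ref_codon and v.alt_codon else None
            ),
            "aa_change": v.aa_change,
            "effect": v.effect,
            "shared": len(carriers) > 1,
            "reference_heteroplasmy": reference_sample in carriers,
        }
        for s in samples:
            if s in rec["support"]:
                a, t = rec["support"][s]
                row[s] = f"{a}/{t}"
                if s != reference_sample:
                    counts[s] += 1
            else:
                row[s] = ""
        row["min_allele_fraction"] = min(
            a / t for a, t in rec["support"].values()
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    return CrossSampleReport(table=table, variant_counts=counts,
                             reference_sample=reference_sample)


def calls_from_variant_table(df: pd.DataFrame, samples: Sequence[str]) -> dict[str, list[VariantCall]]:
    """Build per-sample calls from a printed variant table.

    Expects columns ``position gene ref alt ts_tv codon_index ref_codon
    alt_codon aa_change effect`` plus ``<sample>_alt``/``<sample>_total``
    count pairs (blank = site not called in that sample).
    """
    out: dict[str, list[VariantCall]] = {s: [] for s in samples}
    for _, row in df.iterrows():
        for s in samples:
            alt_reads = row.get(f"{s}_alt")
            total = row.get(f"{s}_total")
            if pd.isna(alt_reads) or pd.isna(total):
                continue
            out[s].append(VariantCall(
                position=int(row["position"]), gene=row["gene"],
                ref_base=row["ref"], alt_base=row["alt"],
                alt_reads=int(alt_reads), total_reads=int(total),
                substitution_class=row["ts_tv"],
                codon_index=int(row["codon_index"]),
                ref_codon=row["ref_codon"], alt_codon=row["alt_codon"],
                aa_change=row["aa_change"], effect=row["effect"],
            ))
    return out
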