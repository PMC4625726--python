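"""Domain types and coordinate arithmetic for circular mitochondrial genomes.

Conventions used throughout the package:

* Coordinates are 1-based, fully closed intervals on the heavy (H) strand,
  the way mitogenome annotation tables are printed.
* A feature crossing the replication origin is stored with ``end`` greater
  than the genome length and normalized modulo the circle on access.
* Light (L) strand features are annotated by their H-strand footprint; their
  coding sequence is the reverse complement of that footprint.
* The genetic code defaults to the vertebrate mitochondrial code (NCBI
  translation table 2), under which ATA encodes Met, TGA encodes Trp and
  AGA/AGG are stop codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO_CODE",
    "GeneAnnotation",
    "CircularMitogenome",
    "reverse_complement",
    "read_annotation_table",
    "write_annotation_table",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "extract_gene_sequence",
    "translate",
    "position_to_codon",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Bases over which compositions and codons are defined.
BASES = "ACGT"

STRANDS = ("H", "L")
FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "CR")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

# NCBI translation table 2 (vertebrate mitochondrial), amino acids in the
# canonical codon order with bases cycling T, C, A, G ('*' marks stops).
_TABLE2_AAS = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
_NCBI_BASE_ORDER = "TCAG"


def _codon_table_from_aa_string(aas: str) -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _NCBI_BASE_ORDER:
        for b2 in _NCBI_BASE_ORDER:
            for b3 in _NCBI_BASE_ORDER:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon genetic code; stops are represented as ``'*'``."""

    table: dict[str, str]
    id: int

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon.upper()) == "*"

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for ``codon``; 'X' for any non-ACGT codon."""
        codon = codon.upper()
        return self.table.get(codon, "X")


VERTEBRATE_MITO_CODE = GeneticCode(table=_codon_table_from_aa_string(_TABLE2_AAS), id=2)


# ---------------------------------------------------------------------------
# Annotations and genomes
# ---------------------------------------------------------------------------

_INCOMPLETE_STOPS = {"T--", "TA-"}


@dataclass
class GeneAnnotation:
    """One feature row of a mitogenome annotation table.

    ``start``/``end`` are 1-based inclusive H-strand coordinates; a feature
    wrapping across the origin carries ``end > genome length``.
    """

    name: str
    start: int
    end: int
    strand: str
    feature_type: str
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) < start ({self.start}); represent "
                "origin-spanning features with end > genome length"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.name}: unknown strand {self.strand!r} (use H or L)")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"{self.name}: unknown feature type {self.feature_type!r}")
        if self.feature_type == "CDS" and not self.start_codon:
            raise ValueError(f"{self.name}: CDS features must carry a start codon")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        """Whether mitogenome coordinate ``pos`` falls inside the feature."""
        if self.start <= pos <= self.end:
            return True
        if genome_length is not None and self.end > genome_length:
            # wrap-around feature: the tail lives at the start of the circle
            return 1 <= pos <= self.end - genome_length
        return False


@dataclass
class CircularMitogenome:
    """Circular H-strand nucleotide sequence plus an ordered annotation table."""

    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    name: str = "mitogenome"
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        self.annotations = sorted(self.annotations, key=lambda a: a.start)
        for a in self.annotations:
            if a.start > len(self.sequence):
                raise ValueError(f"{a.name}: start {a.start} beyond genome length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneAnnotation:
        for a in self.annotations:
            if a.name == name:
                return a
        raise KeyError(name)

    def features_at(self, pos: int, feature_type: str | None = None) -> list[GeneAnnotation]:
        hits = [a for a in self.annotations if a.contains(pos, self.length)]
        if feature_type is not None:
            hits = [a for a in hits if a.feature_type == feature_type]
        return hits


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["name", "start", "end", "strand", "feature_type", "start_codon", "stop_codon"]


def read_annotation_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSV annotation table into a start-sorted list of features.

    The file must carry the header ``name start end strand feature_type
    start_codon stop_codon``; empty codon cells mean "absent". An empty file
    (header only) yields an empty list.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str}, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    anns: list[GeneAnnotation] = []
    for _, row in df.iterrows():
        anns.append(
            GeneAnnotation(
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                feature_type=str(row["feature_type"]),
                start_codon=str(row["start_codon"]) or None,
                stop_codon=str(row["stop_codon"]) or None,
            )
        )
    names = [a.name for a in anns]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicated feature names {sorted(dupes)}")
    return sorted(anns, key=lambda a: a.start)


def write_annotation_table(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "name": a.name,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "feature_type": a.feature_type,
            "start_codon": a.start_codon or "",
            "stop_codon": a.stop_codon or "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> str:
    """First record of a FASTA file as an uppercase nucleotide string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_fasta(seq: str, path: str | Path, name: str = "mitogenome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


_GENBANK_TYPE_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def read_genbank(path: str | Path) -> CircularMitogenome:
    """Load a GenBank flat file, mapping CDS/tRNA/rRNA/D-loop features.

    Start and stop codons of CDS features are inferred from the sequence
    (an out-of-frame trailing T or TA becomes an incomplete stop).
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"))
    seq = str(record.seq).upper()
    anns: list[GeneAnnotation] = []
    for feat in record.features:
        ftype = _GENBANK_TYPE_MAP.get(feat.type)
        if ftype is None:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or ftype
        )
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "L" if feat.location.strand == -1 else "H"
        ann = GeneAnnotation(
            name=name,
            start=start,
            end=end,
            strand=strand,
            feature_type=ftype,
            start_codon="NNN" if ftype == "CDS" else None,
        )
        if ftype == "CDS":
            cds = seq[start - 1 : end] if strand == "H" else reverse_complement(seq[start - 1 : end])
            ann.start_codon = cds[:3]
            tail = len(cds) % 3
            if tail == 1 and cds.endswith("T"):
                ann.stop_codon = "T--"
            elif tail == 2 and cds.endswith("TA"):
                ann.stop_codon = "TA-"
            elif tail == 0 and VERTEBRATE_MITO_CODE.is_stop(cds[-3:]):
                ann.stop_codon = cds[-3:]
        anns.append(ann)
    return CircularMitogenome(sequence=seq, annotations=anns, name=record.id)


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------


def extract_gene_sequence(genome: CircularMitogenome | str, g: GeneAnnotation) -> str:
    """Coding-strand sequence of a feature.

    H-strand features return the genome slice; L-strand features return its
    reverse complement. Features with ``end > length`` wrap across the origin.
    """
    seq = genome.sequence if isinstance(genome, CircularMitogenome) else genome
    n = len(seq)
    if g.start > n:
        raise ValueError(f"{g.name}: start {g.start} outside genome of length {n}")
    if g.length_nt > n:
        raise ValueError(f"{g.name}: feature longer than the genome")
    if g.end <= n:
        sub = seq[g.start - 1 : g.end]
    else:
        sub = seq[g.start - 1 :] + seq[: g.end - n]
    return sub if g.strand == "H" else reverse_complement(sub)


def translate(
    cds: str,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
    incomplete_stop: bool = False,
) -> str:
    """Translate a coding sequence; one letter per complete codon.

    A terminal stop codon is excluded from the returned peptide. Internal
    stops are reported in place as ``'*'`` rather than silently dropped;
    codons containing N (or any non-ACGT base) become ``'X'``. With
    ``incomplete_stop`` the trailing 1-2 nucleotides (a polyadenylation-
    completed stop) are ignored.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"coding sequence shorter than one codon ({len(cds)} nt)")
    tail = len(cds) % 3
    if tail:
        if not incomplete_stop:
            raise ValueError(f"length {len(cds)} is not a multiple of 3; pass incomplete_stop=True")
        cds = cds[:-tail]
    aas = [code.amino_acid(cds[i : i + 3]) for i in range(0, len(cds), 3)]
    if aas and aas[-1] == "*":  # terminal stop is excluded, internal stops stay
        aas.pop()
    return "".join(aas)


def position_to_codon(g: GeneAnnotation, pos: int) -> tuple[int, int]:
    """Map a mitogenome coordinate to (codon_index, offset) within a CDS.

    Offsets are 1..3 within the codon on the coding strand: for H-strand
    genes ``gene_pos = pos - start + 1``; for L-strand genes the reading
    direction is reversed, ``gene_pos = end - pos + 1``.
    """
    if g.feature_type != "CDS":
        raise ValueError(f"{g.name}: position_to_codon requires a CDS feature")
    if not (g.start <= pos <= g.end):
        raise ValueError(f"position {pos} outside {g.name} ({g.start}..{g.end})")
    gene_pos = pos - g.start + 1 if g.strand == "H" else g.end - pos + 1
    codon_index = math.ceil(gene_pos / 3)
    offset = (gene_pos - 1) % 3 + 1
    return codon_index, offset
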