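"""Derived statistics over a mitogenome annotation table.

Reproduces the arithmetic behind a printed mitogenome organization table:
feature lengths, protein lengths implied by the stop-codon class, signed
intergenic spacers (negative = overlap) and genome-level tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GeneAnnotation

__all__ = [
    "classify_stop",
    "aa_length",
    "feature_lengths",
    "intergenic_gaps",
    "trna_length_zscore",
    "AnnotationSummary",
    "summarize_annotation",
]

COMPLETE_STOPS = {"TAA", "TAG", "AGA", "AGG"}
INCOMPLETE_STOPS = {"T--", "TA-"}


def classify_stop(stop_codon: str | None) -> str:
    """Classify a stop codon as ``complete``, ``incomplete`` or ``none``.

    Incomplete stops (T-- / TA-) are gene-boundary T or TA runs completed to
    TAA by polyadenylation of the transcript.
    """
    if stop_codon is None or stop_codon == "":
        return "none"
    stop_codon = stop_codon.upper()
    if stop_codon in COMPLETE_STOPS:
        return "complete"
    if stop_codon in INCOMPLETE_STOPS:
        return "incomplete"
    raise ValueError(f"unrecognized stop codon {stop_codon!r}")


def aa_length(length_nt: int, stop_class: str) -> int:
    """Residue count of a CDS from its nucleotide length and stop class.

    A complete terminal stop occupies a codon that is not translated
    (n/3 - 1 residues); an incomplete stop leaves floor(n/3) full codons,
    all translated.
    """
    if stop_class == "complete":
        if length_nt % 3:
            raise ValueError(f"complete-stop CDS length {length_nt} is not a multiple of 3")
        return length_nt // 3 - 1
    return length_nt // 3


def feature_lengths(table: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Per-feature nucleotide length and, for CDS, residue count and stop class."""
    rows = []
    for a in table:
        row: dict = {"name": a.name, "feature_type": a.feature_type, "strand": a.strand,
                     "length_nt": a.length_nt, "aa_length": pd.NA, "stop_class": pd.NA}
        if a.feature_type == "CDS":
            if a.length_nt < 6:
                raise ValueError(f"{a.name}: CDS of {a.length_nt} nt cannot hold start and stop")
            stop_class = classify_stop(a.stop_codon)
            row["stop_class"] = stop_class
            row["aa_length"] = aa_length(a.length_nt, stop_class)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["aa_length"] = df["aa_length"].astype("Int64")
    return df


def intergenic_gaps(table: Sequence[GeneAnnotation], genome_length: int) -> pd.Series:
    """Signed spacer before each feature: start(i) - end(i-1) - 1.

    The gap is attributed to the downstream feature; the first feature's gap
    is computed circularly from the last feature's end. Negative values are
    overlaps and are never clipped.
    """
    starts = [a.start for a in table]
    if starts != sorted(starts):
        raise ValueError("annotation table must be sorted by start coordinate")
    gaps = []
    for i, a in enumerate(table):
        if i == 0:
            prev_end = table[-1].end - genome_length  # unwrap across the origin
        else:
            prev_end = table[i - 1].end
        gaps.append(a.start - prev_end - 1)
    return pd.Series(gaps, index=[a.name for a in table], name="intergenic_gap")


def trna_length_zscore(
    query_length: float, reference_lengths: Iterable[float], ddof: int = 0
) -> float:
    """z-score of a tRNA length against a reference collection of lengths.

    Uses the population standard deviation by default (``ddof=0``); pass
    ``ddof=1`` for the sample convention.
    """
    ref = np.asarray(list(reference_lengths), dtype=float)
    if ref.size < 2:
        raise ValueError("need at least two reference lengths")
    sd = ref.std(ddof=ddof)
    if sd == 0:
        raise ValueError("reference lengths have zero variance")
    return float((query_length - ref.mean()) / sd)


@dataclass
class AnnotationSummary:
    """Per-feature derived columns plus genome-level tallies."""

    per_feature: pd.DataFrame
    genome_length: int
    counts_by_type: dict[str, int]
    counts_by_strand: dict[str, int]
    control_region_length: int | None

    @property
    def length_plus_gaps(self) -> int:
        """Sum of feature lengths and signed gaps; equals genome length on a circle."""
        return int(self.per_feature["length_nt"].sum() + self.per_feature["intergenic_gap"].sum())


def summarize_annotation(table: Sequence[GeneAnnotation], genome_length: int) -> AnnotationSummary:
    table = sorted(table, key=lambda a: a.start)
    df = feature_lengths(table)
    df["start"] = [a.start for a in table]
    df["end"] = [a.end for a in table]
    df["intergenic_gap"] = intergenic_gaps(table, genome_length).to_numpy()
    counts_type: dict[str, int] = {}
    counts_strand: dict[str, int] = {}
    cr_len = None
    for a in table:
        counts_type[a.feature_type] = counts_type.get(a.feature_type, 0) + 1
        counts_strand[a.strand] = counts_strand.get(a.strand, 0) + 1
        if a.feature_type == "CR":
            cr_len = a.length_nt
    return AnnotationSummary(
        per_feature=df,
        genome_length=genome_length,
        counts_by_type=counts_type,
        counts_by_strand=counts_strand,
        control_region_length=cr_len,
    )
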