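"""Strand-asymmetry and codon-level composition statistics.

Implements the compositional quantities used to compare mitogenomes:
single-strand base fractions, GC/AT skews ((G-C)/(G+C) and (A-T)/(A+T) as
printed — note that part of the literature uses the opposite sign
convention), codon-position GC (GC1/GC2/GC3 in percent, overall coding GC as
a fraction), codon and amino-acid usage, correspondence analysis of count
tables, codon-position stripping of alignments and Spearman rank
correlation with an exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import BASES, GeneticCode, VERTEBRATE_MITO_CODE, translate

__all__ = [
    "CompositionProfile",
    "composition",
    "trim_cds",
    "CodonPositionProfile",
    "codon_position_profile",
    "codon_usage",
    "amino_acid_usage",
    "rscu",
    "CAResult",
    "correspondence_analysis",
    "strip_codon_position",
    "rank_correlation",
]

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


@dataclass(frozen=True)
class CompositionProfile:
    """Base fractions and strand skews of a single sequence.

    Fractions are over called (non-N) bases and sum to 1. A skew whose
    denominator is zero is reported as NaN with the corresponding flag set.
    """

    fA: float
    fC: float
    fG: float
    fT: float
    n_called: int

    @property
    def gc(self) -> float:
        return self.fG + self.fC

    @property
    def gc_skew(self) -> float:
        denom = self.fG + self.fC
        return (self.fG - self.fC) / denom if denom > 0 else math.nan

    @property
    def at_skew(self) -> float:
        denom = self.fA + self.fT
        return (self.fA - self.fT) / denom if denom > 0 else math.nan

    @property
    def gc_skew_defined(self) -> bool:
        return self.fG + self.fC > 0

    @property
    def at_skew_defined(self) -> bool:
        return self.fA + self.fT > 0


def composition(seq: str) -> CompositionProfile:
    """Base fractions and skews of ``seq``; N bases are excluded throughout."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in BASES}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence has no called (A/C/G/T) bases")
    return CompositionProfile(
        fA=counts["A"] / n, fC=counts["C"] / n, fG=counts["G"] / n, fT=counts["T"] / n,
        n_called=n,
    )


def trim_cds(cds: str, drop_complete_stop: bool = True,
             code: GeneticCode = VERTEBRATE_MITO_CODE) -> str:
    """Trim a CDS to complete sense codons.

    Trailing 1-2 nt (an incomplete, polyadenylation-completed stop) are
    always dropped; a terminal complete stop codon is dropped unless
    ``drop_complete_stop`` is False.
    """
    cds = cds.upper()
    tail = len(cds) % 3
    if tail:
        cds = cds[:-tail]
    if drop_complete_stop and len(cds) >= 3 and code.is_stop(cds[-3:]):
        cds = cds[:-3]
    return cds


@dataclass
class CodonPositionProfile:
    """Per-codon-position base composition of a coding-gene set.

    ``counts`` is a 3x4 table (codon position x base); GCp values are in
    percent, ``coding_gc`` is the overall G+C fraction of the concatenation —
    the mixed units conventional in mitogenome composition tables.
    """

    counts: pd.DataFrame  # index: position 1..3, columns: A C G T
    n_codons: int

    def fractions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def gc_percent(self, position: int) -> float:
        row = self.counts.loc[position]
        return 100.0 * (row["G"] + row["C"]) / row.sum()

    @property
    def gc1(self) -> float:
        return self.gc_percent(1)

    @property
    def gc2(self) -> float:
        return self.gc_percent(2)

    @property
    def gc3(self) -> float:
        return self.gc_percent(3)

    @property
    def coding_gc(self) -> float:
        total = self.counts.to_numpy().sum()
        gc = self.counts[["G", "C"]].to_numpy().sum()
        return gc / total


def codon_position_profile(cds_set: Iterable[str]) -> CodonPositionProfile:
    """Base tallies per codon position over a set of in-frame coding sequences.

    Each sequence must already be trimmed to a multiple of 3 (see
    :func:`trim_cds`); codons containing N are excluded entirely.
    """
    counts = np.zeros((3, 4), dtype=int)
    base_index = {b: i for i, b in enumerate(BASES)}
    n_codons = 0
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"coding sequence of length {len(cds)} is out of frame")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if any(b not in base_index for b in codon):
                continue
            n_codons += 1
            for p, b in enumerate(codon):
                counts[p, base_index[b]] += 1
    df = pd.DataFrame(counts, index=[1, 2, 3], columns=list(BASES))
    return CodonPositionProfile(counts=df, n_codons=n_codons)


def codon_usage(cds_set: Iterable[str], code: GeneticCode = VERTEBRATE_MITO_CODE,
                include_stops: bool = False) -> pd.Series:
    """Codon counts over a set of in-frame coding sequences.

    Returns a 64-long integer Series indexed by codon. Stop codons are
    excluded unless ``include_stops``; codons containing N are skipped.
    """
    counts = dict.fromkeys(ALL_CODONS, 0)
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"coding sequence of length {len(cds)} is out of frame")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon not in counts:
                continue
            if not include_stops and code.is_stop(codon):
                continue
            counts[codon] += 1
    return pd.Series(counts, name="count")


def amino_acid_usage(usage: pd.Series, code: GeneticCode = VERTEBRATE_MITO_CODE) -> pd.Series:
    """Marginalize a codon-usage table to amino-acid counts ('*' = stop)."""
    aa = pd.Series({codon: code.amino_acid(codon) for codon in usage.index}, name="aa")
    return usage.groupby(aa).sum().rename("count")


def rscu(usage: pd.Series, code: GeneticCode = VERTEBRATE_MITO_CODE) -> pd.Series:
    """Relative synonymous codon usage: count / mean count of its synonyms."""
    aa = pd.Series({codon: code.amino_acid(codon) for codon in usage.index})
    means = usage.groupby(aa).transform("mean")
    with np.errstate(invalid="ignore"):
        out = usage / means
    return out.rename("rscu")


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class CAResult:
    """Correspondence analysis of a nonnegative contingency table.

    Row/column principal coordinates, per-axis principal inertias
    (squared singular values) and the total inertia (chi-square / n).
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    row_masses: np.ndarray = field(repr=False, default=None)
    col_masses: np.ndarray = field(repr=False, default=None)

    @property
    def principal_inertias(self) -> np.ndarray:
        return self.singular_values**2

    @property
    def total_inertia(self) -> float:
        return float((self.singular_values**2).sum())

    @property
    def inertia_fractions(self) -> np.ndarray:
        tot = self.total_inertia
        return self.principal_inertias / tot if tot > 0 else self.principal_inertias


def correspondence_analysis(matrix: pd.DataFrame | np.ndarray) -> CAResult:
    """Standard correspondence analysis via SVD of standardized residuals.

    With correspondence matrix P = N / n, row masses r and column masses c,
    the residual matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is factorized
    as S = U diag(s) V^T; principal coordinates are F = D_r^{-1/2} U diag(s)
    for rows and G = D_c^{-1/2} V diag(s) for columns. Total inertia equals
    the Pearson chi-square statistic of the table divided by its grand total.
    """
    if isinstance(matrix, pd.DataFrame):
        N = matrix.to_numpy(dtype=float)
        row_names = list(matrix.index)
        col_names = list(matrix.columns)
    else:
        N = np.asarray(matrix, dtype=float)
        row_names = [f"r{i}" for i in range(N.shape[0])]
        col_names = [f"c{j}" for j in range(N.shape[1])]
    if N.ndim != 2 or N.size == 0:
        raise ValueError("need a 2-D nonempty count matrix")
    if (N < 0).any():
        raise ValueError("counts must be nonnegative")
    if (N.sum(axis=1) == 0).any() or (N.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column in the count table")
    n = N.sum()
    if n == 0:
        raise ValueError("rank-0 matrix: grand total is zero")
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(N.shape) - 1  # trivial dimension removed by centering
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    F = U * s / np.sqrt(r)[:, None]
    G = Vt.T * s / np.sqrt(c)[:, None]
    axes = [f"axis{i+1}" for i in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(F, index=row_names, columns=axes),
        col_coords=pd.DataFrame(G, index=col_names, columns=axes),
        singular_values=s,
        row_masses=r,
        col_masses=c,
    )


# ---------------------------------------------------------------------------
# Alignment codon-position stripping
# ---------------------------------------------------------------------------


def strip_codon_position(alignment: Sequence[str], position: int) -> list[str]:
    """Remove one codon position's columns from an in-frame codon alignment.

    ``alignment`` is a list of equal-length gapped sequences whose width is a
    multiple of 3; column triplets are codons. Returns sequences of 2/3 the
    input width. The result is no longer translatable — downstream code must
    treat it as nucleotide data only.
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    if not alignment:
        return []
    width = len(alignment[0])
    if width % 3:
        raise ValueError(f"alignment width {width} is not a multiple of 3")
    if any(len(s) != width for s in alignment):
        raise ValueError("alignment rows differ in length")
    keep = [i for i in range(width) if i % 3 != position - 1]
    return ["".join(s[i] for i in keep) for s in alignment]


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_correlation(x: Sequence[float], y: Sequence[float],
                     exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p-value at small n.

    For n <= ``exact_max_n`` the two-sided p-value is the exact fraction of
    the n! permutations of y whose |rho| is at least the observed |rho|;
    beyond that, scipy's asymptotic p-value is used. Ties are handled with
    midranks; a constant vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
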