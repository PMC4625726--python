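"""Bundled reference tables for the Austrolebias charrua mitogenome (KP718940).

The package ships the published annotation of the 17,271-bp reference
mitogenome and the published table of heteroplasmic variants found in three
full siblings (samples AUS4, AUS5 and the reference individual AUS7). Only
coordinates, codons and read counts are bundled — not the genome sequence,
which lives in GenBank under accession KP718940.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .model import GeneAnnotation, read_annotation_table

REFERENCE_SAMPLE = "AUS7"
SAMPLES = ("AUS4", "AUS5", "AUS7")

#: Total length of the reference mitogenome in bp.
GENOME_LENGTH = 17271


def _data_path(filename: str) -> Path:
    return Path(resources.files("mitoasym").joinpath("data", filename))


def reference_annotation_path() -> Path:
    return _data_path("kp718940_annotation.tsv")


def reference_annotation() -> list[GeneAnnotation]:
    """The 38 annotated features of the reference mitogenome, start-sorted."""
    return read_annotation_table(reference_annotation_path())


def reference_derived_columns() -> pd.DataFrame:
    """Published per-feature sizes, residue counts and intergenic spacers."""
    df = pd.read_csv(_data_path("kp718940_derived.tsv"), sep="\t")
    return df


def reference_variants() -> pd.DataFrame:
    """Published heteroplasmic variant table (one row per site).

    ``self_consistent`` is 0 for the two printed rows whose codon-change
    column is internally inconsistent with the stated gene coordinates
    (positions 5690 and 12764); those rows are kept for accounting but must
    not be used as codon-arithmetic fixtures.
    """
    df = pd.read_csv(_data_path("kp718940_variants.tsv"), sep="\t")
    df["self_consistent"] = df["self_consistent"].astype(bool)
    return df
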