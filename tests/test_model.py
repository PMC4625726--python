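"""Coordinate arithmetic, translation and annotation IO."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitoasym.model import (
    CircularMitogenome,
    GeneAnnotation,
    VERTEBRATE_MITO_CODE,
    extract_gene_sequence,
    position_to_codon,
    read_annotation_table,
    reverse_complement,
    translate,
    write_annotation_table,
)

ANN_HEADER = "name\tstart\tend\tstrand\tfeature_type\tstart_codon\tstop_codon\n"


def _write(tmp_path, rows):
    p = tmp_path / "ann.tsv"
    p.write_text(ANN_HEADER + "".join(rows))
    return p


class TestAnnotationTable:
    def test_reads_rows_and_sorts_by_start(self, tmp_path):
        p = _write(tmp_path, [
            "tRNA-Cys\t5343\t5399\tL\ttRNA\t\t\n",
            "ND1\t2854\t3828\tH\tCDS\tATG\tTAA\n",
        ])
        anns = read_annotation_table(p)
        assert [a.name for a in anns] == ["ND1", "tRNA-Cys"]
        assert anns[0].length_nt == 975
        assert anns[1].length_nt == 57

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = _write(tmp_path, [])
        assert read_annotation_table(p) == []

    @pytest.mark.parametrize("row,msg", [
        ("ND1\t3828\t2854\tH\tCDS\tATG\tTAA\n", "end"),
        ("ND1\t2854\t3828\tZ\tCDS\tATG\tTAA\n", "strand"),
    ])
    def test_invalid_rows_rejected(self, tmp_path, row, msg):
        p = _write(tmp_path, [row])
        with pytest.raises(ValueError, match=msg):
            read_annotation_table(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = _write(tmp_path, [
            "ND1\t10\t30\tH\tCDS\tATG\tTAA\n",
            "ND1\t40\t60\tH\tCDS\tATG\tTAA\n",
        ])
        with pytest.raises(ValueError, match="duplicated"):
            read_annotation_table(p)

    def test_round_trip(self, tmp_path, ref_annotations):
        p = tmp_path / "out.tsv"
        write_annotation_table(ref_annotations, p)
        back = read_annotation_table(p)
        assert [(a.name, a.start, a.end, a.strand) for a in back] == [
            (a.name, a.start, a.end, a.strand) for a in ref_annotations
        ]


class TestExtractGeneSequence:
    def test_h_strand_slice(self):
        g = CircularMitogenome("ACGTACGT")
        ann = GeneAnnotation("x", 2, 4, "H", "rRNA")
        assert extract_gene_sequence(g, ann) == "CGT"

    def test_l_strand_is_reverse_complement(self):
        g = CircularMitogenome("ACGTACGT")
        ann = GeneAnnotation("x", 2, 4, "L", "rRNA")
        assert extract_gene_sequence(g, ann) == "ACG"

    def test_wraparound_matches_rotation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            seq = "".join(rng.choice(list("ACGT"), n))
            start = int(rng.integers(2, n + 1))
            end = start + int(rng.integers(1, n - 1))
            ann = GeneAnnotation("w", start, end, "H", "rRNA")
            # oracle: rotate the circle so the feature is contiguous
            rotated = seq[start - 1 :] + seq[: start - 1]
            assert extract_gene_sequence(CircularMitogenome(seq), ann) == rotated[: end - start + 1]

    def test_h_and_l_extractions_are_reverse_complements(self, toy_genome):
        for a in toy_genome.annotations:
            flipped = GeneAnnotation(a.name, a.start, a.end,
                                     "L" if a.strand == "H" else "H",
                                     a.feature_type, a.start_codon or "ATG")
            assert extract_gene_sequence(toy_genome, a) == reverse_complement(
                extract_gene_sequence(toy_genome, flipped)
            )

    def test_out_of_range_feature_rejected(self):
        g = CircularMitogenome("ACGTACGT")
        with pytest.raises(ValueError):
            extract_gene_sequence(g, GeneAnnotation("x", 9, 10, "H", "rRNA"))


class TestTranslate:
    def test_complete_stop_excluded(self):
        assert translate("ATGTTTTAA") == "MF"

    def test_vertebrate_mito_reassignments(self):
        assert translate("ATA") == "M"
        assert translate("TGA") == "W"
        assert VERTEBRATE_MITO_CODE.is_stop("AGA")
        assert VERTEBRATE_MITO_CODE.is_stop("AGG")

    def test_internal_stop_reported_in_place(self):
        assert translate("ATGTAAATG") == "M*M"

    def test_ambiguous_codon_is_x(self):
        assert translate("ATGNNNTAA") == "MX"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")

    def test_incomplete_stop_length_rule(self, toy_genome):
        """n/3 - 1 residues for complete stops, floor(n/3) for incomplete."""
        for a in toy_genome.annotations:
            if a.feature_type != "CDS":
                continue
            cds = extract_gene_sequence(toy_genome, a)
            incomplete = a.stop_codon in ("T--", "TA-")
            prot = translate(cds, incomplete_stop=incomplete)
            expected = len(cds) // 3 if incomplete else len(cds) // 3 - 1
            assert len(prot) == expected, a.name
            assert "*" not in prot, a.name


class TestPositionToCodon:
    @pytest.mark.parametrize("gene,pos,expected", [
        ("ND2", 4105, (22, 2)),
        ("COI", 6245, (260, 3)),
        ("Cytb", 15735, (368, 1)),
    ])
    def test_published_coordinates(self, ref_annotations, gene, pos, expected):
        ann = next(a for a in ref_annotations if a.name == gene)
        assert position_to_codon(ann, pos) == expected

    def test_gene_start_is_codon_one(self, ref_annotations):
        for a in ref_annotations:
            if a.feature_type == "CDS":
                assert position_to_codon(a, a.start if a.strand == "H" else a.end) == (1, 1)

    def test_outside_gene_rejected(self, ref_annotations):
        nd1 = next(a for a in ref_annotations if a.name == "ND1")
        with pytest.raises(ValueError):
            position_to_codon(nd1, nd1.end + 1)

    def test_non_cds_rejected(self, ref_annotations):
        trna = next(a for a in ref_annotations if a.feature_type == "tRNA")
        with pytest.raises(ValueError):
            position_to_codon(trna, trna.start)

    def test_codon_round_trip_reproduces_genome_base(self, toy_genome):
        """The base at (codon_index, offset) of the extracted gene equals the
        genome base (H strand) or its complement (L strand)."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(1)
        for a in toy_genome.annotations:
            if a.feature_type != "CDS":
                continue
            gene_seq = extract_gene_sequence(toy_genome, a)
            for pos in rng.integers(a.start, a.end + 1, size=40):
                pos = int(pos)
                ci, off = position_to_codon(a, pos)
                base_in_gene = gene_seq[(ci - 1) * 3 + off - 1]
                genome_base = toy_genome.sequence[pos - 1]
                expected = genome_base if a.strand == "H" else comp[genome_base]
                assert base_in_gene == expected


@given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
def test_reverse_complement_is_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_genbank_reader_recovers_annotation(tmp_path, toy_genome):
    """A GenBank flat file written from the synthetic genome reads back with
    identical coordinates/strands and correctly inferred start/stop codons."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    from mitoasym.model import read_genbank

    rec = SeqRecord(Seq(toy_genome.sequence), id="SYNTH1", name="SYNTH1",
                    description="synthetic toy mitogenome",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    tmap = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    for a in toy_genome.annotations:
        rec.features.append(SeqFeature(
            SimpleLocation(a.start - 1, a.end, strand=-1 if a.strand == "L" else 1),
            type=tmap[a.feature_type], qualifiers={"gene": [a.name]}))
    path = tmp_path / "synth.gb"
    SeqIO.write(rec, path, "genbank")

    back = read_genbank(path)
    assert back.sequence == toy_genome.sequence
    key = lambda anns: {(a.name, a.start, a.end, a.strand, a.feature_type) for a in anns}
    assert key(back.annotations) == key(toy_genome.annotations)
    stops = {a.name: (a.start_codon, a.stop_codon)
             for a in back.annotations if a.feature_type == "CDS"}
    expected = {a.name: (a.start_codon, a.stop_codon)
                for a in toy_genome.annotations if a.feature_type == "CDS"}
    assert stops == expected
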