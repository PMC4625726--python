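"""Pileup parsing, the filter cascade, effect annotation, cross-sample report."""

import numpy as np
import pandas as pd
import pytest

from _caller_oracle import fuzz_column, oracle_accepts
from mitoasym.hetcall import (
    CallerParams,
    CandidateCall,
    PileupColumn,
    PileupParseError,
    ReadObservation,
    Rejection,
    VariantCall,
    annotate_call,
    call_column,
    call_pileup,
    calls_from_variant_table,
    classify_effect,
    cross_sample_report,
    parse_pileup,
    transition_or_transversion,
)
from mitoasym.model import extract_gene_sequence, position_to_codon, translate


def obs(base="A", strand="forward", bq=40, mq=60, d5=20, d3=20, read_id=None, **kw):
    return ReadObservation(base=base, strand=strand, base_quality=bq,
                           mapping_quality=mq, dist_to_5prime=d5,
                           dist_to_3prime=d3, read_id=read_id, **kw)


def column(ref="A", n_ref=50, alt=None, n_alt=0, alt_strands=("forward", "reverse"),
           pos=100, **alt_kw):
    observations = [obs(base=ref, strand="forward" if i % 2 else "reverse")
                    for i in range(n_ref)]
    for i in range(n_alt):
        observations.append(obs(base=alt, strand=alt_strands[i % len(alt_strands)], **alt_kw))
    return PileupColumn(position=pos, ref_base=ref, observations=observations)


class TestParsePileup:
    def test_plain_dialect(self):
        cols = parse_pileup("mt\t100\tA\t4\t..,,\tIIII\n")
        c = cols[0]
        assert c.position == 100 and c.ref_base == "A" and c.depth == 4
        assert sum(o.strand == "forward" for o in c.observations) == 2
        assert all(o.base == "A" for o in c.observations)
        assert all(o.base_quality == 40 for o in c.observations)
        assert all(o.dist_to_5prime is None for o in c.observations)

    def test_low_quality_alt_fails_q30_gate(self):
        cols = parse_pileup("mt\t100\tA\t3\t.C,\tI#I\n")
        c_obs = next(o for o in cols[0].observations if o.base == "C")
        assert c_obs.base_quality == 2
        gated = [o for o in cols[0].observations
                 if o.base_quality >= 30]
        assert all(o.base == "A" for o in gated)

    def test_read_start_end_and_indel_syntax(self):
        line = "mt\t5\tG\t5\t^I..+2ATt$,*\tIIIII\n"
        c = parse_pileup(line)[0]
        assert c.depth == 5
        assert c.observations[0].mapping_quality == ord("I") - 33
        assert c.observations[1].has_indel
        assert c.observations[2].base == "T" and c.observations[2].strand == "reverse"
        assert c.observations[4].is_deletion

    def test_depth_mismatch_reports_line_number(self):
        with pytest.raises(PileupParseError, match="line 2"):
            parse_pileup("mt\t1\tA\t1\t.\tI\nmt\t2\tA\t3\t..\tII\n")

    def test_read_tracking_propagates_mapping_quality(self):
        text = ("mt\t1\tA\t1\t^].\tI\n"
                "mt\t2\tC\t2\t.^F,\tII\n"
                "mt\t3\tG\t2\t.$,$\tII\n")
        cols = parse_pileup(text)
        assert cols[1].observations[0].mapping_quality == ord("]") - 33
        assert cols[2].observations[1].mapping_quality == ord("F") - 33
        # read ids persist across columns
        assert cols[0].observations[0].read_id == cols[2].observations[0].read_id


class TestCallColumn:
    def test_coverage_boundary(self):
        col = column(n_ref=17, alt="G", n_alt=2)  # gated depth 19
        res = call_column(col)
        assert isinstance(res, Rejection) and res.reason == "min_coverage"
        col = column(n_ref=18, alt="G", n_alt=2)  # gated depth 20
        assert isinstance(call_column(col), CandidateCall)

    def test_single_strand_support_rejected(self):
        col = column(n_ref=48, alt="G", n_alt=2, alt_strands=("forward",))
        res = call_column(col)
        assert res.reason == "strand_requirement"

    def test_two_alternative_bases_rejected_as_multiallelic(self):
        col = column(n_ref=46, alt="G", n_alt=2)
        col.observations += [obs(base="T", strand=s) for s in ("forward", "reverse")]
        assert call_column(col).reason == "multiallelic"

    def test_one_supporting_read_rejected(self):
        col = column(n_ref=49, alt="G", n_alt=1)
        assert call_column(col).reason == "min_alt_reads"

    def test_published_style_column_accepted_with_allele_fraction(self):
        col = column(ref="T", n_ref=49, alt="C", n_alt=44)
        res = call_column(col)
        assert isinstance(res, CandidateCall)
        assert res.alt_reads == 44 and res.total_reads == 93
        assert res.allele_fraction == pytest.approx(44 / 93)

    def test_alt_near_read_end_dropped_from_support(self):
        col = column(n_ref=48, alt="G", n_alt=2, d5=1)
        assert call_column(col).reason == "read_end_distance"
        col = column(n_ref=48, alt="G", n_alt=2, d5=5, d3=5)
        assert isinstance(call_column(col), CandidateCall)

    def test_unknown_distances_pass_end_filter(self):
        col = column(n_ref=48, alt="G", n_alt=2, d5=None, d3=None)
        assert isinstance(call_column(col), CandidateCall)

    def test_noisy_neighborhood_drops_supporting_read(self):
        col = column(n_ref=48, alt="G", n_alt=2, read_id=None)
        col.observations[-1].read_id = "r1"
        col.observations[-2].read_id = "r2"
        neighbor = PileupColumn(position=102, ref_base="C", observations=[
            obs(base="T", read_id="r1"),  # r1 mismatches 2 bp away
            obs(base="C", read_id="r2"),
        ])
        context = {100: col, 102: neighbor}
        assert call_column(col, context=context).reason == "neighborhood"
        neighbor.observations[0].base = "C"
        assert isinstance(call_column(col, context=context), CandidateCall)

    def test_low_quality_support_is_invisible(self):
        col = column(n_ref=50, alt="G", n_alt=5, bq=10)
        assert call_column(col).reason == "no_alt"


class TestOracleEquivalence:
    def test_fuzzed_columns_match_brute_force(self):
        rng = np.random.default_rng(2024)
        params = CallerParams(min_coverage=10)
        both = 0
        for _ in range(300):
            col = fuzz_column(rng)
            res = call_column(col, params)
            expected = oracle_accepts(col, params)
            if isinstance(res, CandidateCall):
                assert res.alt_base == expected
                both += 1
            else:
                assert expected is None, (res, expected)
        assert both > 10  # the fuzzer must actually produce accepted columns

    def test_threshold_monotonicity(self):
        """Raising a count-type threshold never grows the accepted set.

        Quality-gate thresholds are excluded on purpose: stricter gating can
        remove a competing alternative base and so turn a multiallelic
        rejection into an accept — a real, intended property of the
        single-alternative criterion, not a defect.
        """
        rng = np.random.default_rng(7)
        base = CallerParams(min_coverage=10)
        stricter = [
            CallerParams(min_coverage=20),
            CallerParams(min_coverage=10, min_alt_reads=3),
            CallerParams(min_coverage=10, min_read_end_distance=12),
        ]
        cols = [fuzz_column(rng) for _ in range(400)]
        accepted = {i for i, col in enumerate(cols)
                    if isinstance(call_column(col, base), CandidateCall)}
        for params in stricter:
            tighter = {i for i, col in enumerate(cols)
                       if isinstance(call_column(col, params), CandidateCall)}
            assert tighter <= accepted


class TestEffectAnnotation:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "Ts"), ("C", "T", "Ts"), ("C", "A", "Tv"), ("G", "T", "Tv"),
    ])
    def test_transition_transversion(self, ref, alt, expected):
        assert transition_or_transversion(ref, alt) == expected

    @pytest.mark.parametrize("ref_codon,alt_codon,expected", [
        ("TCG", "TAG", "nonsense"),   # Ser -> STOP
        ("CAA", "CAG", "synonymous"),  # Gln -> Gln
        ("TTT", "CTT", "non-synonymous"),  # Phe -> Leu
        ("ATT", "ATA", "non-synonymous"),  # Ile -> Met under the mito code
    ])
    def test_effect_classes(self, ref_codon, alt_codon, expected):
        assert classify_effect(ref_codon, alt_codon) == expected

    def test_annotation_matches_mutated_translation(self, toy_genome):
        """Oracle: mutate the genome, re-extract and re-translate the gene;
        the annotated alt codon and effect must agree."""
        rng = np.random.default_rng(3)
        checked = 0
        for a in toy_genome.annotations:
            if a.feature_type != "CDS":
                continue
            for pos in rng.integers(a.start, a.end + 1, size=25):
                pos = int(pos)
                ref = toy_genome.sequence[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                call = CandidateCall(position=pos, ref_base=ref, alt_base=alt,
                                     alt_reads=5, total_reads=50,
                                     alt_forward=3, alt_reverse=2, filtered_support=5)
                (vc,) = annotate_call(call, toy_genome)
                assert vc.gene == a.name
                ci, off = position_to_codon(a, pos)
                assert (vc.codon_index, vc.codon_offset) == (ci, off)
                if vc.effect == "incomplete-codon":
                    continue
                mutated = (toy_genome.sequence[: pos - 1] + alt + toy_genome.sequence[pos:])
                mutant_gene = extract_gene_sequence(mutated, a)
                assert vc.alt_codon == mutant_gene[(ci - 1) * 3 : ci * 3]
                checked += 1
        assert checked > 50

    def test_noncoding_position_passed_through(self, toy_genome):
        cr = toy_genome.feature("CR")
        pos = cr.start + 5
        call = CandidateCall(position=pos, ref_base=toy_genome.sequence[pos - 1],
                             alt_base="A" if toy_genome.sequence[pos - 1] != "A" else "C",
                             alt_reads=3, total_reads=30, alt_forward=2,
                             alt_reverse=1, filtered_support=3)
        (vc,) = annotate_call(call, toy_genome)
        assert vc.gene is None and vc.effect == "non-coding"


class TestCrossSampleReport:
    def _call(self, pos, ref="T", alt="C", alt_reads=10, total=100, gene="G1"):
        return VariantCall(position=pos, gene=gene, ref_base=ref, alt_base=alt,
                           alt_reads=alt_reads, total_reads=total,
                           substitution_class="Ts", effect="synonymous")

    def test_shared_and_reference_flags(self):
        report = cross_sample_report({
            "S1": [self._call(100), self._call(200)],
            "S2": [self._call(100, alt_reads=20)],
            "REF": [self._call(100, alt_reads=30)],
        }, reference_sample="REF")
        t = report.table.set_index("position")
        assert bool(t.loc[100, "shared"]) and bool(t.loc[100, "reference_heteroplasmy"])
        assert not bool(t.loc[200, "shared"])
        assert report.variant_counts == {"S1": 2, "S2": 1}
        assert report.n_sample_site_pairs == 3
        assert t.loc[100, "min_allele_fraction"] == pytest.approx(0.1)

    def test_single_sample_empty_report(self):
        report = cross_sample_report({"S1": []})
        assert report.table.empty and report.n_sample_site_pairs == 0

    def test_inconsistent_reference_allele_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cross_sample_report({
                "S1": [self._call(100, ref="T")],
                "S2": [self._call(100, ref="G")],
            })

    def test_calls_from_printed_table(self):
        df = pd.DataFrame([{
            "position": 10, "gene": "X", "ref": "A", "alt": "G", "ts_tv": "Ts",
            "codon_index": 4, "ref_codon": "AAA", "alt_codon": "GAA",
            "aa_change": "Lys to Glu", "effect": "non-synonymous",
            "S1_alt": 3, "S1_total": 30, "S2_alt": None, "S2_total": None,
        }])
        calls = calls_from_variant_table(df, ["S1", "S2"])
        assert len(calls["S1"]) == 1 and calls["S2"] == []
        assert calls["S1"][0].allele_fraction == pytest.approx(0.1)
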