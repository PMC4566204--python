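"""ORF scanning, the lncRNA filter, localization and categorization rules."""
import pytest
from hypothesis import given, settings, strategies as st

from synterna.align import PairwiseHit, revcomp
from synterna.annotate import (LocationRejection, TranscriptLocation,
                               classify_lnc, flag_mirna_precursor,
                               is_lnc_candidate, locate_transcript, max_orf_aa,
                               relative_direction, scan_orfs)

from conftest import make_annotation


class TestScanOrfs:
    def test_simple_forward_orf(self):
        reports = scan_orfs("ATGAAATAA")
        assert [(r.frame, r.orf_length_aa) for r in reports] == [(1, 2)]

    def test_no_atg_no_orf(self):
        assert scan_orfs("CCCCCC") == []

    def test_reverse_strand_orf(self):
        # reverse complement of TTATTTCAT is ATGAAATAA
        reports = scan_orfs("TTATTTCAT")
        assert [(r.frame, r.orf_length_aa) for r in reports] == [(-1, 2)]

    def test_orf_without_stop_runs_to_sequence_end(self):
        reports = scan_orfs("ATGAAAAAA")
        assert max(r.orf_length_aa for r in reports if r.frame == 1) == 3

    def test_empty_sequence(self):
        assert scan_orfs("") == []

    def test_rejects_invalid_characters(self):
        with pytest.raises(ValueError):
            scan_orfs("ATGXXX")

    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reverse_complement_symmetry(self, seq):
        """Same multiset of ORF lengths on a sequence and its reverse
        complement, with frame signs flipped."""
        fwd = scan_orfs(seq)
        rev = scan_orfs(revcomp(seq))
        assert sorted((r.orf_length_aa, r.frame > 0) for r in fwd) == \
            sorted((r.orf_length_aa, r.frame < 0) for r in rev)


class TestLncFilter:
    def _seq_with_orf(self, length_nt, orf_aa):
        # ATG + (orf_aa-1) AAA codons + TAA, padded with C to length
        core = "ATG" + "AAA" * (orf_aa - 1) + "TAA"
        assert len(core) <= length_nt
        return core + "C" * (length_nt - len(core))

    @pytest.mark.parametrize("length,orf_aa,expected", [
        (550, 60, True),
        (150, 10, False),   # too short
        (800, 120, False),  # ORF too long
        (199, 10, False), (200, 10, True),   # length boundary
        (600, 99, True), (600, 100, False),  # ORF boundary
    ])
    def test_thresholds(self, length, orf_aa, expected):
        seq = self._seq_with_orf(length, orf_aa)
        reports = scan_orfs(seq)
        assert max_orf_aa(reports) >= orf_aa
        assert is_lnc_candidate(seq, reports) is expected


def _hit(span, qlen=1000, subject="chr1", sstart=5000):
    return PairwiseHit("t", subject, 100.0 * span / qlen, span, 2 * span,
                       1e-30, qstart=0, qend=span, sstart=sstart,
                       send=sstart + span)


class TestLocateTranscript:
    def test_single_covering_hsp_accepted(self):
        loc = locate_transcript("t", 1000, [_hit(550)])
        assert isinstance(loc, TranscriptLocation)
        assert (loc.chrom_id, loc.start, loc.end) == ("chr1", 5000, 5550)

    def test_two_hsps_rejected(self):
        rej = locate_transcript("t", 1000, [_hit(600), _hit(600, subject="chr2")])
        assert isinstance(rej, LocationRejection) and rej.reason == "multi_hsp"

    def test_low_coverage_rejected(self):
        rej = locate_transcript("t", 1000, [_hit(400)])
        assert isinstance(rej, LocationRejection) and rej.reason == "low_coverage"

    def test_no_hit_rejected(self):
        rej = locate_transcript("t", 1000, [])
        assert isinstance(rej, LocationRejection) and rej.reason == "no_hit"


class TestClassify:
    def _annot(self):
        return make_annotation(genes=[("g1", 10_000, 12_000, "+"),
                                      ("g2", 30_000, 32_000, "-")])

    def _loc(self, start, end, strand="+"):
        return TranscriptLocation("chr1", start, end, strand)

    @pytest.mark.parametrize("gap,expected", [
        (600, "LINC"), (500, "LINC"), (499, "GATU"),
    ])
    def test_distance_boundaries(self, gap, expected):
        category, gene, dist = classify_lnc(self._loc(12_000 + gap, 13_000 + gap),
                                            self._annot())
        assert (category, gene, dist) == (expected, "g1", gap)

    def test_antisense_overlap_is_nat(self):
        category, gene, dist = classify_lnc(self._loc(11_000, 11_500, "-"),
                                            self._annot())
        assert (category, gene, dist) == ("NAT", "g1", 0)

    def test_sense_overlap_is_gatu_not_nat(self):
        category, _, dist = classify_lnc(self._loc(11_000, 11_500, "+"),
                                         self._annot())
        assert (category, dist) == ("GATU", 0)

    def test_no_genes_unclassifiable(self):
        category, gene, _ = classify_lnc(self._loc(100, 700),
                                         make_annotation(genes=[]))
        assert category == "unclassifiable" and gene is None

    def test_nearest_gene_tie_breaks_on_id(self):
        annot = make_annotation(genes=[("gB", 10_000, 11_000, "+"),
                                       ("gA", 13_000, 14_000, "+")])
        # TU equidistant (gap 400) from both genes
        _, gene, dist = classify_lnc(self._loc(11_400, 12_600), annot)
        assert gene == "gA" and dist == 400

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distance_invariant_under_coordinate_shift(self, shift):
        annot = make_annotation(length=200_000,
                                genes=[("g1", 10_000 + shift, 12_000 + shift, "+")])
        _, _, dist = classify_lnc(self._loc(13_000 + shift, 13_600 + shift), annot)
        assert dist == 1000


class TestRelativeDirection:
    def test_plus_strand_gene(self):
        from synterna.annotate import GeneFeature
        gene = GeneFeature("g", "chr1", 10_000, 12_000, "+")
        assert relative_direction(8_000, 8_500, "+", gene) == "upstream"
        assert relative_direction(13_000, 13_500, "+", gene) == "downstream"
        assert relative_direction(11_000, 11_500, "-", gene) == "antisense"
        assert relative_direction(11_000, 11_500, "+", gene) == "overlapping"

    def test_minus_strand_gene_flips_sides(self):
        from synterna.annotate import GeneFeature
        gene = GeneFeature("g", "chr1", 10_000, 12_000, "-")
        assert relative_direction(13_000, 13_500, "+", gene) == "upstream"
        assert relative_direction(8_000, 8_500, "+", gene) == "downstream"


class TestMirnaFlag:
    def _db(self, rng):
        from conftest import random_dna
        from synterna.align import SequenceDatabase
        ref = random_dna(rng, 80)
        return ref, SequenceDatabase({"mir1": ref})

    def test_hit_and_stable_mfe(self, rng):
        ref, db = self._db(rng)
        assert flag_mirna_precursor("CCC" + ref + "GGG", db, -71.8) is True

    def test_mfe_outside_window(self, rng):
        ref, db = self._db(rng)
        assert flag_mirna_precursor("CCC" + ref + "GGG", db, -10.0) is False
        assert flag_mirna_precursor("CCC" + ref + "GGG", db, -90.0) is False

    def test_no_reference_hit(self, rng):
        from conftest import random_dna
        _, db = self._db(rng)
        assert flag_mirna_precursor(random_dna(rng, 300), db, -50.0) is False

    def test_empty_reference_db(self):
        assert flag_mirna_precursor("ACGT" * 100, None, -50.0) is False
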