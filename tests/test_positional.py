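"""Positional-conservation calls, summaries, telomere statistics."""
import pytest

from synterna.annotate import (GeneFeature, LncCandidate, TranscriptLocation,
                               relative_direction)
from synterna.positional import (PositionalCall, positional_call,
                                 summarize_positional, telomere_proximity)
from synterna.synteny import chain_anchors, find_anchors

from conftest import make_annotation


def candidate(tid, species, start, end, strand="+", gene=None, direction="",
              category="LINC", distance=1000):
    return LncCandidate(
        transcript_id=tid, species_id=species,
        location=TranscriptLocation("chr1", start, end, strand),
        category=category, nearest_gene_id=gene, distance_bp=distance,
        transcript_length_nt=end - start, max_orf_aa=10,
        relative_direction=direction)


def collinear_pair(n=8, inverted=False, strand_a="+", gene_len=1000, gap=3000):
    """Two annotations with orthologous genes gA{i} <-> gB{i}; optionally the
    B genome carries the whole segment inverted (order and strands flipped)."""
    step = gene_len + gap
    genes_a = [(f"gA{i}", i * step, i * step + gene_len, strand_a)
               for i in range(n)]
    if inverted:
        flip = "-" if strand_a == "+" else "+"
        genes_b = [(f"gB{i}", (n - 1 - i) * step, (n - 1 - i) * step + gene_len,
                    flip) for i in range(n)]
    else:
        genes_b = [(f"gB{i}", i * step, i * step + gene_len, strand_a)
                   for i in range(n)]
    a = make_annotation("spA", length=n * step + gap, genes=genes_a)
    b = make_annotation("spB", length=n * step + gap, genes=genes_b)
    anchors = find_anchors(a, b, [(f"gA{i}", f"gB{i}") for i in range(n)])
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    return a, b, blocks


class TestPositionalCall:
    def test_conserved_upstream_lnc_found(self):
        a, b, blocks = collinear_pair()
        # lnc 1 kb upstream of gA3 (strand +, so upstream = left)
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gA3",
                          direction="upstream")
        target = [candidate("spB|L1", "spB", 10_400, 10_900, gene="gB3",
                            direction="upstream")]
        call = positional_call(query, a, b, blocks, target)
        assert call.status == "positionally_conserved"
        assert call.relative_direction == "upstream"
        assert call.matched_lnc_id == "spB|L1"

    def test_direction_mismatch_not_matched(self):
        a, b, blocks = collinear_pair()
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gA3",
                          direction="upstream")
        # target lnc lies downstream of gB3 instead
        target = [candidate("spB|L1", "spB", 13_100, 13_600, gene="gB3",
                            direction="downstream")]
        call = positional_call(query, a, b, blocks, target)
        assert call.status == "not_found"

    def test_empty_target_set_is_never_conserved(self):
        a, b, blocks = collinear_pair()
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gA3",
                          direction="upstream")
        assert positional_call(query, a, b, blocks, []).status == "not_found"

    def test_anchor_absent_from_blocks_is_no_synteny(self):
        a, b, blocks = collinear_pair()
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gZZ",
                          direction="upstream")
        assert positional_call(query, a, b, blocks, []).status == "no_synteny"

    def test_unlocated_lnc(self):
        a, b, blocks = collinear_pair()
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene=None)
        assert positional_call(query, a, b, blocks, []).status == "anchor_unlocated"

    def test_inverted_block_orientation_corrected(self):
        """An upstream lnc matches a target lnc that sits on the other
        physical side in raw coordinates: the inversion flips the anchor
        strand too, so the relative direction is preserved."""
        a, b, blocks = collinear_pair(inverted=True)
        assert blocks[0].orientation == "inverted"
        # upstream of gA3 (+): left of gene at 12000..13000
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gA3",
                          direction="upstream")
        # gB3 sits at (8-1-3)*4000=16000..17000 on '-'; upstream = right side
        gB3 = GeneFeature("gB3", "chr1", 16_000, 17_000, "-")
        assert relative_direction(17_200, 17_700, "+", gB3) == "upstream"
        target = [candidate("spB|L1", "spB", 17_200, 17_700, gene="gB3",
                            direction="upstream")]
        call = positional_call(query, a, b, blocks, target)
        assert call.status == "positionally_conserved"

    def test_far_away_target_lnc_outside_window(self):
        a, b, blocks = collinear_pair()
        query = candidate("spA|L1", "spA", 10_500, 11_000, gene="gA3",
                          direction="upstream")
        # a target lnc upstream of a *different* gene, far from gB3's window
        target = [candidate("spB|LX", "spB", 26_500, 27_000, gene="gB7",
                            direction="upstream")]
        assert positional_call(query, a, b, blocks, target).status == "not_found"


class TestSummarize:
    def _call(self, lnc, status, target="spB"):
        return PositionalCall(lnc, "spA", target, status)

    def test_fractions_per_lineage(self):
        calls = []
        for i in range(9):
            status = "positionally_conserved" if i < 3 else "not_found"
            calls.append(self._call(f"L{i}", status))
            calls.append(self._call(f"L{i}", "not_found", target="spC"))
        summary = summarize_positional(calls, {f"L{i}": "Cleomaceae"
                                               for i in range(9)})
        (row,) = summary.per_lineage
        assert row.n_lineage_specific == 9
        assert row.n_positionally_conserved == 3
        assert row.pct_positional == pytest.approx(33.333, abs=0.01)

    def test_positive_anywhere_counts_once(self):
        calls = [self._call("L0", "not_found"),
                 self._call("L0", "positionally_conserved", target="spC")]
        summary = summarize_positional(calls, {"L0": "X"})
        assert summary.dual_class_loci == ["L0"]

    def test_no_calls_empty_summary(self):
        summary = summarize_positional([], {})
        assert summary.per_lineage == [] and summary.dual_class_loci == []


class TestTelomere:
    def test_distance_arithmetic(self):
        report = telomere_proximity(
            [("L1", "chr1", 1_200_000, 1_205_000),
             ("L2", "chr1", 14_997_500, 15_002_500)],
            {"chr1": 30_000_000})
        assert report.loci[0][2] == 1_200_000
        assert report.n_within == 1 and report.n_total == 2

    def test_threshold_inclusive(self):
        report = telomere_proximity([("L1", "chr1", 2_500_000, 2_600_000)],
                                    {"chr1": 30_000_000})
        assert report.n_within == 1  # distance exactly 2,500,000

    def test_eight_of_twelve(self):
        loci = [(f"L{i}", "chr1", 1_000_000, 1_001_000) for i in range(8)]
        loci += [(f"M{i}", "chr1", 15_000_000, 15_001_000) for i in range(4)]
        report = telomere_proximity(loci, {"chr1": 30_000_000})
        assert report.fraction_within == pytest.approx(8 / 12)

    def test_reflection_symmetry(self, rng):
        """fraction_within is invariant under reflecting every locus through
        the chromosome midpoint."""
        length = 30_000_000
        loci = []
        for i in range(30):
            start = int(rng.integers(0, length - 10_000))
            loci.append((f"L{i}", "chr1", start, start + 5_000))
        mirrored = [(l, c, length - e, length - s) for l, c, s, e in loci]
        a = telomere_proximity(loci, {"chr1": length})
        b = telomere_proximity(mirrored, {"chr1": length})
        assert a.fraction_within == b.fraction_within

    def test_out_of_bounds_locus_is_error(self):
        with pytest.raises(ValueError):
            telomere_proximity([("L1", "chr1", -5, 100)], {"chr1": 1000})
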