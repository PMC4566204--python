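"""Gene ranks, anchor chaining DP vs exhaustive enumeration, projection."""
import itertools

import pytest

from synterna.synteny import (SyntenyAnchor, SyntenyBlock, build_gene_order,
                              chain_anchors, chain_score, find_anchors,
                              project_region)

from conftest import make_annotation


def anchor(ra, rb, gene_a=None, gene_b=None, **kw):
    return SyntenyAnchor(gene_a or f"a{ra}", gene_b or f"b{rb}", ra, rb,
                         "chrA", "chrB", **kw)


def brute_force_best_chain(anchors, max_gap, min_anchors):
    """Enumerate every monotone chain (both orientations) by DFS; returns the
    best score among chains with >= min_anchors, or None."""
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].order_index_a,
                                  anchors[i].order_index_b))
    best = None

    def ok(prev, cur, orientation):
        if cur.order_index_a <= prev.order_index_a:
            return False
        if orientation == "same" and cur.order_index_b <= prev.order_index_b:
            return False
        if orientation == "inverted" and cur.order_index_b >= prev.order_index_b:
            return False
        if cur.order_index_a - prev.order_index_a - 1 > max_gap:
            return False
        if abs(cur.order_index_b - prev.order_index_b) - 1 > max_gap:
            return False
        return True

    def extend(chain, rest, orientation):
        nonlocal best
        if len(chain) >= min_anchors:
            sc = chain_score(chain)
            if best is None or sc > best:
                best = sc
        for k, idx in enumerate(rest):
            cand = anchors[idx]
            if not chain or ok(chain[-1], cand, orientation):
                extend(chain + [cand], rest[k + 1:], orientation)

    for orientation in ("same", "inverted"):
        extend([], order, orientation)
    return best


class TestGeneOrder:
    def test_ranks_follow_start_coordinates(self):
        annot = make_annotation(genes=[("g1", 100, 600, "+"),
                                       ("g2", 900, 1400, "+"),
                                       ("g3", 5000, 5500, "-")])
        assert build_gene_order(annot)["chr1"] == {"g1": 0, "g2": 1, "g3": 2}

    def test_empty_chromosome(self):
        assert build_gene_order(make_annotation(genes=[]))["chr1"] == {}

    def test_tied_starts_break_on_gene_id(self):
        annot = make_annotation(genes=[("gB", 100, 600, "+"),
                                       ("gA", 100, 700, "+")])
        assert build_gene_order(annot)["chr1"] == {"gA": 0, "gB": 1}


class TestFindAnchors:
    def _pair(self):
        a = make_annotation("spA", genes=[(f"a{i}", i * 1000, i * 1000 + 500, "+")
                                          for i in range(5)])
        b = make_annotation("spB", genes=[(f"b{i}", i * 1000, i * 1000 + 500, "+")
                                          for i in range(5)])
        return a, b

    def test_one_anchor_per_pair(self):
        a, b = self._pair()
        anchors = find_anchors(a, b, [(f"a{i}", f"b{i}") for i in range(5)])
        assert len(anchors) == 5
        assert all(x.order_index_a == x.order_index_b for x in anchors)

    def test_many_to_many_pairs_all_kept(self):
        a, b = self._pair()
        anchors = find_anchors(a, b, [("a0", "b0"), ("a0", "b3")])
        assert len(anchors) == 2

    def test_no_pairs_no_anchors(self):
        a, b = self._pair()
        assert find_anchors(a, b, []) == []


class TestChaining:
    def test_perfectly_collinear_single_block(self):
        blocks = chain_anchors([anchor(i, i) for i in range(5)], min_anchors=4)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert len(blocks[0].anchors) == 5
        assert blocks[0].score == 5.0

    def test_exact_reversal_is_inverted(self):
        blocks = chain_anchors([anchor(i, 4 - i) for i in range(5)],
                               min_anchors=4)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_large_gap_splits_blocks(self):
        ranks = [0, 1, 2, 3, 34, 35, 36, 37]  # rank gap of 30 in the middle
        blocks = chain_anchors([anchor(r, r) for r in ranks],
                               max_gap_genes=20, min_anchors=4)
        assert [len(b.anchors) for b in blocks] == [4, 4]

    def test_matches_exhaustive_enumeration(self, rng):
        """DP chain score equals brute-force best over 200 random instances
        of up to 10 anchors."""
        for _ in range(200):
            n = int(rng.integers(2, 11))
            max_gap = int(rng.integers(2, 8))
            ra = rng.choice(20, size=n, replace=False)
            rb = rng.choice(20, size=n, replace=False)
            anchors = [anchor(int(x), int(y), gene_a=f"a{k}", gene_b=f"b{k}")
                       for k, (x, y) in enumerate(zip(ra, rb))]
            blocks = chain_anchors(anchors, max_gap_genes=max_gap,
                                   min_anchors=2)
            expected = brute_force_best_chain(anchors, max_gap, 2)
            if expected is None:
                assert blocks == []
            else:
                assert blocks, f"expected a chain scoring {expected}"
                assert blocks[0].score == pytest.approx(expected)

    def test_block_invariants_assertable(self):
        with pytest.raises(ValueError):
            SyntenyBlock("b", [anchor(0, 1), anchor(1, 0)], "same", 2.0)


class TestProjection:
    def _fixture(self, inverted=False):
        n = 6
        a = make_annotation("spA", genes=[(f"a{i}", i * 2000, i * 2000 + 1000, "+")
                                          for i in range(n)])
        if inverted:
            genes_b = [(f"b{i}", (n - 1 - i) * 2000, (n - 1 - i) * 2000 + 1000,
                        "-") for i in range(n)]
        else:
            genes_b = [(f"b{i}", i * 2000, i * 2000 + 1000, "+")
                       for i in range(n)]
        b = make_annotation("spB", genes=genes_b)
        anchors = find_anchors(a, b, [(f"a{i}", f"b{i}") for i in range(n)])
        blocks = chain_anchors(anchors, min_anchors=4)
        assert len(blocks) == 1
        return a, b, blocks[0]

    def test_anchor_gene_projects_onto_partner(self):
        _, b, block = self._fixture()
        region = project_region(("chr1", 4000, 5000), block, b)
        assert region is not None
        assert region.start <= 4000 and region.end >= 5000

    def test_query_between_anchors_inverted_block(self):
        """With an inverted block, the interval between anchors i and i+1
        maps between the partners of i+1 and i (coordinates swap)."""
        _, b, block = self._fixture(inverted=True)
        assert block.orientation == "inverted"
        region = project_region(("chr1", 5200, 5800), block, b)  # between a2, a3
        # partners: b2 spans [6000,7000), b3 spans [4000,5000)
        assert (region.start, region.end) == (4000, 7000)
        assert region.orientation == "inverted"

    def test_region_outside_block_has_no_projection(self):
        _, b, block = self._fixture()
        assert project_region(("chrZ", 0, 100), block, b) is None

    def test_round_trip_contains_original_gene(self):
        a, b, block = self._fixture()
        fwd = project_region(("chr1", 4000, 5000), block, b)
        # build the reverse block and map back
        anchors_rev = find_anchors(b, a, [(f"b{i}", f"a{i}") for i in range(6)])
        block_rev = chain_anchors(anchors_rev, min_anchors=4)[0]
        back = project_region(("chr1", fwd.start, fwd.end), block_rev, a)
        assert back.start <= 4000 and back.end >= 5000
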