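"""Anchor-gene collinearity between two annotated genomes.

Chaining runs in gene-rank space (robust to intergenic-length noise): anchors
are homologous gene pairs carrying their order index along each chromosome,
and collinear blocks are maximum-score chains under a DAGchainer-style model
(+1 per anchor, gap penalty 0.05 per skipped rank, both orientations).  A
block supports projecting a query region of genome A into genome B through
its flanking anchors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GeneFeature, GenomeAnnotation

DEFAULT_MAX_GAP_GENES = 20
DEFAULT_MIN_ANCHORS = 4
GAP_PENALTY_PER_RANK = 0.05


@dataclass
class SyntenyAnchor:
    gene_a_id: str
    gene_b_id: str
    order_index_a: int
    order_index_b: int
    chrom_a: str
    chrom_b: str
    # gene coordinates, attached so blocks can project regions
    a_start: int = 0
    a_end: int = 0
    a_strand: str = "+"
    b_start: int = 0
    b_end: int = 0
    b_strand: str = "+"
    weight: float = 1.0


@dataclass
class SyntenyBlock:
    block_id: str
    anchors: list[SyntenyAnchor]
    orientation: str  # "same" | "inverted"
    score: float

    def __post_init__(self) -> None:
        ra = [a.order_index_a for a in self.anchors]
        rb = [a.order_index_b for a in self.anchors]
        if ra != sorted(ra) or len(set(ra)) != len(ra):
            raise ValueError(f"block {self.block_id}: a-ranks not strictly increasing")
        inc = all(x < y for x, y in zip(rb, rb[1:]))
        dec = all(x > y for x, y in zip(rb, rb[1:]))
        if self.orientation == "same" and not inc:
            raise ValueError(f"block {self.block_id}: b-ranks not increasing")
        if self.orientation == "inverted" and not dec:
            raise ValueError(f"block {self.block_id}: b-ranks not decreasing")


@dataclass
class ProjectedRegion:
    chrom: str
    start: int
    end: int
    orientation: str  # "same" | "inverted"


def build_gene_order(annotation: GenomeAnnotation) -> dict[str, dict[str, int]]:
    """Dense rank (0..n-1) of protein-coding genes per chromosome, ordered by
    (start, gene_id)."""
    ranks: dict[str, dict[str, int]] = {}
    for chrom_id, _ in annotation.chromosomes:
        genes = sorted(annotation.coding_genes(chrom_id),
                       key=lambda g: (g.start, g.gene_id))
        ranks[chrom_id] = {g.gene_id: i for i, g in enumerate(genes)}
    return ranks


def find_anchors(annotation_a: GenomeAnnotation, annotation_b: GenomeAnnotation,
                 gene_homology_pairs: list[tuple[str, str]] | list[tuple[str, str, float]]
                 ) -> list[SyntenyAnchor]:
    """One anchor per homologous gene pair, with ranks and coordinates
    attached; many-to-many pairs are all retained (chaining resolves them)."""
    ranks_a = build_gene_order(annotation_a)
    ranks_b = build_gene_order(annotation_b)
    genes_a = {g.gene_id: g for g in annotation_a.coding_genes()}
    genes_b = {g.gene_id: g for g in annotation_b.coding_genes()}
    anchors = []
    for pair in gene_homology_pairs:
        ga_id, gb_id = pair[0], pair[1]
        weight = float(pair[2]) if len(pair) > 2 else 1.0
        ga = genes_a.get(ga_id)
        gb = genes_b.get(gb_id)
        if ga is None or gb is None:
            continue
        anchors.append(SyntenyAnchor(
            gene_a_id=ga_id, gene_b_id=gb_id,
            order_index_a=ranks_a[ga.chrom_id][ga_id],
            order_index_b=ranks_b[gb.chrom_id][gb_id],
            chrom_a=ga.chrom_id, chrom_b=gb.chrom_id,
            a_start=ga.start, a_end=ga.end, a_strand=ga.strand,
            b_start=gb.start, b_end=gb.end, b_strand=gb.strand,
            weight=weight,
        ))
    anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.order_index_a,
                                a.order_index_b))
    return anchors


def chain_score(chain: list[SyntenyAnchor]) -> float:
    """+1 per anchor, minus 0.05 per skipped gene rank on either genome
    between consecutive anchors.  Shared by the DP and the test oracles."""
    score = float(len(chain))
    for prev, cur in zip(chain, chain[1:]):
        gap_a = abs(cur.order_index_a - prev.order_index_a) - 1
        gap_b = abs(cur.order_index_b - prev.order_index_b) - 1
        score -= GAP_PENALTY_PER_RANK * (gap_a + gap_b)
    return score


def _collapse_tandem(anchors: list[SyntenyAnchor]) -> list[SyntenyAnchor]:
    """Collapse runs of anchors sharing a gene on either side to the
    best-weight one (prevents tandem duplicates inflating chains)."""
    best_by_a: dict[tuple[str, str], SyntenyAnchor] = {}
    for a in anchors:
        key = (a.gene_a_id, a.chrom_b)
        cur = best_by_a.get(key)
        if cur is None or a.weight > cur.weight:
            best_by_a[key] = a
    stage = list(best_by_a.values())
    best_by_b: dict[tuple[str, str], SyntenyAnchor] = {}
    for a in stage:
        key = (a.gene_b_id, a.chrom_a)
        cur = best_by_b.get(key)
        if cur is None or a.weight > cur.weight:
            best_by_b[key] = a
    out = list(best_by_b.values())
    out.sort(key=lambda x: (x.order_index_a, x.order_index_b))
    return out


def _best_chain(anchors: list[SyntenyAnchor], orientation: str,
                max_gap_genes: int) -> tuple[list[int], float]:
    """Best chain by O(n^2) longest-increasing-chain DP over sorted anchors."""
    sign = 1 if orientation == "same" else -1
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].order_index_a,
                                  sign * anchors[i].order_index_b))
    n = len(order)
    score = [1.0] * n
    back = [-1] * n
    for jj in range(n):
        j = order[jj]
        aj, bj = anchors[j].order_index_a, anchors[j].order_index_b
        for ii in range(jj):
            i = order[ii]
            ai, bi = anchors[i].order_index_a, anchors[i].order_index_b
            if ai >= aj:
                continue
            if orientation == "same" and bi >= bj:
                continue
            if orientation == "inverted" and bi <= bj:
                continue
            gap_a = aj - ai - 1
            gap_b = abs(bj - bi) - 1
            if gap_a > max_gap_genes or gap_b > max_gap_genes:
                continue
            cand = score[ii] + 1.0 - GAP_PENALTY_PER_RANK * (gap_a + gap_b)
            if cand > score[jj] + 1e-12:
                score[jj] = cand
                back[jj] = ii
    if n == 0:
        return [], 0.0
    bestj = max(range(n), key=lambda k: (score[k], -k))
    chain_pos = []
    k = bestj
    while k != -1:
        chain_pos.append(order[k])
        k = back[k]
    chain_pos.reverse()
    return chain_pos, score[bestj]


def chain_anchors(anchors: list[SyntenyAnchor],
                  max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
                  min_anchors: int = DEFAULT_MIN_ANCHORS) -> list[SyntenyBlock]:
    """Greedy best-chain extraction per chromosome pair: repeatedly take the
    highest-scoring chain over both orientations, emit it as a block when it
    has at least `min_anchors` anchors, remove its anchors, and repeat."""
    by_pair: dict[tuple[str, str], list[SyntenyAnchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[SyntenyBlock] = []
    counter = 0
    for pair_key in sorted(by_pair):
        remaining = _collapse_tandem(by_pair[pair_key])
        while True:
            best = None
            for orientation in ("same", "inverted"):
                pos, sc = _best_chain(remaining, orientation, max_gap_genes)
                if len(pos) >= min_anchors and (best is None or sc > best[2]):
                    best = (orientation, pos, sc)
            if best is None:
                break
            orientation, pos, sc = best
            chain = [remaining[i] for i in pos]
            blocks.append(SyntenyBlock(
                block_id=f"B{counter:04d}", anchors=chain,
                orientation=orientation, score=round(sc, 6)))
            counter += 1
            picked = set(pos)
            remaining = [a for i, a in enumerate(remaining) if i not in picked]
    return blocks


def project_region(query_region: tuple[str, int, int], block: SyntenyBlock,
                   annotation_b: GenomeAnnotation) -> ProjectedRegion | None:
    """Map a genome-A region through a block to genome B via flanking anchors.

    The projected interval spans the b-side partners of the nearest anchors at
    or beyond the two query edges (order swapped for inverted blocks); regions
    outside the block's a-side span project to None.
    """
    chrom, qstart, qend = query_region
    anchors = [a for a in block.anchors if a.chrom_a == chrom]
    if not anchors:
        return None
    by_bp = sorted(anchors, key=lambda a: (a.a_start, a.a_end))
    overlapping = [a for a in by_bp if a.a_start < qend and a.a_end > qstart]
    if overlapping:
        left, right = overlapping[0], overlapping[-1]
    else:
        left = next((a for a in reversed(by_bp) if a.a_end <= qstart), None)
        right = next((a for a in by_bp if a.a_start >= qend), None)
        if left is None or right is None:
            # query beyond the block's terminal anchor on one side
            return None
    b_lo = min(left.b_start, right.b_start)
    b_hi = max(left.b_end, right.b_end)
    chrom_b = left.chrom_b
    length = annotation_b.chrom_length(chrom_b)
    return ProjectedRegion(chrom_b, max(0, b_lo), min(length, b_hi),
                           block.orientation)
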