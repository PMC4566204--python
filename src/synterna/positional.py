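"""The central call: is a lineage-specific lncRNA conserved by position?

Each lineage-specific lncRNA is anchored on its nearest protein-coding gene.
The anchor is projected into a target genome through the synteny blocks; a
geometric search window around the projected anchor partner (the gene body
extended to the midpoint of the adjacent intergenic interval on the matched
side) is then scanned for a target lncRNA candidate in the same relative
direction (upstream / downstream / antisense, in the local gene's reading
orientation).  Matching directions natively in each genome makes the call
orientation-correct automatically: an inverted block flips both the physical
side and the anchor strand, leaving the relative direction unchanged.

Also here: per-lineage summary percentages and the telomere-proximity
statistic (distance of a locus to the nearest chromosome end).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GenomeAnnotation, LncCandidate, relative_direction
from .synteny import SyntenyBlock, project_region

DEFAULT_TELOMERE_THRESHOLD_BP = 2_500_000


@dataclass
class PositionalCall:
    lnc_id: str
    source_species: str
    target_species: str
    status: str  # positionally_conserved | not_found | no_synteny | anchor_unlocated
    relative_direction: str | None = None
    matched_lnc_id: str | None = None
    anchor_gene_id: str | None = None


@dataclass
class TelomereReport:
    threshold_bp: int
    loci: list[tuple[str, str, int]]  # (lnc_id, chrom, distance_to_nearest_end)
    n_within: int
    n_total: int

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n_total if self.n_total else float("nan")


@dataclass
class LineageSummary:
    lineage: str
    n_lineage_specific: int
    n_positionally_conserved: int

    @property
    def pct_positional(self) -> float:
        if self.n_lineage_specific == 0:
            return float("nan")
        return 100.0 * self.n_positionally_conserved / self.n_lineage_specific


@dataclass
class ConservationSummary:
    per_lineage: list[LineageSummary]
    dual_class_loci: list[str]  # "sequence-diverged, positionally conserved"
    calls: list[PositionalCall] = field(default_factory=list)


def _gene_neighbourhood(gene, annotation: GenomeAnnotation,
                        side: str) -> tuple[int, int]:
    """Gene body extended to the midpoint of the adjacent intergenic interval
    on the requested side ("5p"/"3p" in the gene's reading orientation, or
    "none" for the bare gene body)."""
    start, end = gene.start, gene.end
    if side == "none":
        return start, end
    genes = sorted(annotation.coding_genes(gene.chrom_id),
                   key=lambda g: (g.start, g.gene_id))
    i = next(k for k, g in enumerate(genes) if g.gene_id == gene.gene_id)
    left_physical = (side == "5p") == (gene.strand == "+")
    if left_physical:
        prev_end = genes[i - 1].end if i > 0 else 0
        mid = (prev_end + gene.start) // 2
        return mid, end
    nxt_start = (genes[i + 1].start if i + 1 < len(genes)
                 else annotation.chrom_length(gene.chrom_id))
    mid = (gene.end + nxt_start) // 2
    return start, mid


_SIDE_OF_DIRECTION = {"upstream": "5p", "downstream": "3p",
                      "antisense": "none", "overlapping": "none"}


def positional_call(lnc: LncCandidate, source_annot: GenomeAnnotation,
                    target_annot: GenomeAnnotation,
                    blocks: list[SyntenyBlock],
                    target_lnc_set: list[LncCandidate]) -> PositionalCall:
    """One verdict for one lineage-specific lncRNA in one target genome."""
    base = dict(lnc_id=lnc.transcript_id, source_species=source_annot.species_id,
                target_species=target_annot.species_id,
                anchor_gene_id=lnc.nearest_gene_id)
    if lnc.location is None or lnc.nearest_gene_id is None:
        return PositionalCall(status="anchor_unlocated", **base)
    direction = lnc.relative_direction
    # find a block carrying the anchor gene on its a-side
    anchor_entries = [(b, a) for b in blocks for a in b.anchors
                      if a.gene_a_id == lnc.nearest_gene_id]
    if not anchor_entries:
        return PositionalCall(status="no_synteny",
                              relative_direction=direction, **base)
    block, anchor = anchor_entries[0]
    projected = project_region((anchor.chrom_a, anchor.a_start, anchor.a_end),
                               block, target_annot)
    if projected is None:
        return PositionalCall(status="no_synteny",
                              relative_direction=direction, **base)
    partner = next((g for g in target_annot.coding_genes(anchor.chrom_b)
                    if g.gene_id == anchor.gene_b_id), None)
    if partner is None:
        return PositionalCall(status="no_synteny",
                              relative_direction=direction, **base)
    side = _SIDE_OF_DIRECTION.get(direction, "none")
    win_start, win_end = _gene_neighbourhood(partner, target_annot, side)
    matches = []
    for cand in target_lnc_set:
        loc = cand.location
        if loc.chrom_id != partner.chrom_id:
            continue
        if loc.start >= win_end or loc.end <= win_start:
            continue
        cand_dir = relative_direction(loc.start, loc.end, loc.strand, partner)
        if cand_dir == direction:
            matches.append(cand.transcript_id)
    if matches:
        return PositionalCall(status="positionally_conserved",
                              relative_direction=direction,
                              matched_lnc_id=min(matches), **base)
    return PositionalCall(status="not_found",
                          relative_direction=direction, **base)


def summarize_positional(calls: list[PositionalCall],
                         lineage_of_lnc: dict[str, str]) -> ConservationSummary:
    """Aggregate calls: a locus counts as positionally conserved when at
    least one call in another lineage is positive; percentages are per
    source lineage over that lineage's lineage-specific loci."""
    loci = sorted({c.lnc_id for c in calls})
    positive = sorted({c.lnc_id for c in calls
                       if c.status == "positionally_conserved"})
    per_lineage: dict[str, LineageSummary] = {}
    for lnc_id in loci:
        lin = lineage_of_lnc[lnc_id]
        entry = per_lineage.setdefault(lin, LineageSummary(lin, 0, 0))
        entry.n_lineage_specific += 1
        if lnc_id in positive:
            entry.n_positionally_conserved += 1
    return ConservationSummary(
        per_lineage=[per_lineage[k] for k in sorted(per_lineage)],
        dual_class_loci=positive,
        calls=calls,
    )


def telomere_proximity(loci: list[tuple[str, str, int, int]],
                       chrom_lengths: dict[str, int],
                       threshold_bp: int = DEFAULT_TELOMERE_THRESHOLD_BP
                       ) -> TelomereReport:
    """Distance of each locus (lnc_id, chrom, start, end) to its nearest
    chromosome end; `within` is inclusive at the threshold."""
    rows = []
    n_within = 0
    for lnc_id, chrom, start, end in loci:
        length = chrom_lengths[chrom]
        if start < 0 or end > length:
            raise ValueError(f"locus {lnc_id} outside chromosome {chrom}")
        dist = min(start, length - end)
        if dist <= threshold_bp:
            n_within += 1
        rows.append((lnc_id, chrom, dist))
    return TelomereReport(threshold_bp, rows, n_within, len(loci))
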