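"""Synthetic multi-lineage phylogenomic fixtures with planted lncRNA truth.

The generator emulates the study design of a small plant family comparison:
several lineages of related species share one ancestral gene order
(collinear by construction), protein-coding genes diverge slowly, intergenic
DNA diverges fast (intron-like), and long non-coding RNA loci are planted
next to chosen anchor genes in three conservation classes:

* ``sequence_conserved`` - the locus is sequence-constrained (evolves at the
  coding rate) and is carried and transcribed by every lineage;
* ``positional_only`` - the locus keeps its anchor adjacency and relative
  direction in every lineage but its sequence evolves at the fast intergenic
  rate between lineages, so cross-lineage identity collapses;
* ``private`` - the locus exists (and is transcribed) in exactly one lineage.

Divergence is modelled on a two-level tree: one ancestral genome, a lineage
ancestor mutated at the class rate, and species mutated at
``rate * within_lineage_scale``.  Within-lineage similarity therefore stays
high (species of a lineage share a recent ancestor) while cross-lineage
similarity reflects the class rate - the contrast the downstream pipeline has
to recover.  The mutation model is substitution-only (no indels), so
orthologous coordinates are identical across species and percent identity has
a closed-form expectation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .align import encode, revcomp
from .annotate import GeneFeature, GenomeAnnotation, max_orf_aa, scan_orfs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


class SizingError(ValueError):
    """The configured genome cannot hold the requested planted features."""


@dataclass
class SimConfig:
    seed: int = 42
    lineages: list[tuple[str, int]] = field(default_factory=lambda: [
        ("Brassicaceae", 3), ("Aethionemeae", 2), ("Cleomaceae", 2)])
    genes_per_genome: int = 200
    gene_length_bp: int = 1000
    intergenic_mean_bp: int = 3000
    cds_divergence: float = 0.10
    lnc_divergence: float = 0.40
    n_lnc_sequence_conserved: int = 10
    n_lnc_positional_only: int = 10
    n_lnc_private: int = 10
    lnc_length_bp: int = 500
    chrom_count: int = 1
    within_lineage_scale: float = 0.25
    linc_gap_bp: int = 1000   # planted LINC distance from its anchor
    gatu_gap_bp: int = 100    # planted GATU distance from its anchor
    nat_overlap_bp: int = 200  # NAT overlap into the anchor gene body
    n_coding_transcripts: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.cds_divergence <= 1.0
                and 0.0 <= self.lnc_divergence <= 1.0):
            raise ValueError("divergence probabilities must lie in [0, 1]")
        if self.lnc_divergence < self.cds_divergence:
            raise ValueError("lnc_divergence must be >= cds_divergence "
                             "(intergenic DNA evolves at least as fast as coding)")
        for name in ("genes_per_genome", "gene_length_bp", "intergenic_mean_bp",
                     "n_lnc_sequence_conserved", "n_lnc_positional_only",
                     "n_lnc_private", "lnc_length_bp", "chrom_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def species_ids(self) -> list[str]:
        return [f"{name[:4]}_sp{i + 1}"
                for name, count in self.lineages for i in range(count)]

    @property
    def species_to_lineage(self) -> dict[str, str]:
        return {f"{name[:4]}_sp{i + 1}": name
                for name, count in self.lineages for i in range(count)}


@dataclass
class PlantedLnc:
    truth_id: str
    conservation_class: str  # sequence_conserved | positional_only | private
    category: str            # LINC | GATU | NAT
    relative_direction: str  # upstream | downstream | antisense
    anchor_gene_index: int
    lineages: list[str]
    strand: str
    chrom_id: str = "chr1"
    start: int = 0  # identical in every carrier species (substitution-only)
    end: int = 0


@dataclass
class SyntheticTruth:
    lncs: list[PlantedLnc]

    def by_class(self, conservation_class: str) -> list[PlantedLnc]:
        return [p for p in self.lncs
                if p.conservation_class == conservation_class]

    def get(self, truth_id: str) -> PlantedLnc:
        return next(p for p in self.lncs if p.truth_id == truth_id)


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, dict[str, str]]          # species -> chrom -> sequence
    annotations: dict[str, GenomeAnnotation]
    transcripts: dict[str, dict[str, str]]      # species -> transcript id -> seq
    truth: SyntheticTruth


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability `divergence` to a
    uniformly chosen *different* base; length is unchanged."""
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    codes = encode(seq)
    if codes.size and codes.max() > 3:
        raise ValueError("mutate_sequence: sequence contains non-ACGT characters")
    if codes.size == 0:
        return ""
    hit = rng.random(codes.size) < divergence
    shift = rng.integers(1, 4, size=codes.size)
    out = codes.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return _BASES[out].tobytes().decode("ascii")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_coding_gene(length: int, rng: np.random.Generator) -> str:
    """A gene body holding one long ORF (ATG + non-stop codons + stop) with
    short random flanks, so unmutated transcripts fail the lncRNA ORF filter."""
    flank5 = 30
    n_codons = (length - flank5 - 6 - 30) // 3
    codons = [_NONSTOP_CODONS[k]
              for k in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)]
    core = _random_seq(flank5, rng) + "ATG" + "".join(codons) + "TAA"
    return core + _random_seq(length - len(core), rng)


def _random_lnc(length: int, rng: np.random.Generator, max_aa: int = 60) -> str:
    """Random ancestral lncRNA sequence, rejection-sampled to carry no ORF
    longer than `max_aa` amino acids."""
    for _ in range(200):
        seq = _random_seq(length, rng)
        if max_orf_aa(scan_orfs(seq)) <= max_aa:
            return seq
    raise RuntimeError("could not draw a low-ORF lncRNA sequence")


# --- layout -----------------------------------------------------------------

@dataclass
class _Segment:
    role: str   # "gene" | "spacer" | "lnc"
    length: int
    gene_index: int = -1
    truth_id: str = ""


def _plan_layout(config: SimConfig, rng: np.random.Generator
                 ) -> tuple[list[_Segment], list[PlantedLnc]]:
    """Ancestral layout: alternating spacer/gene segments with lnc loci carved
    out of chosen spacers (or overlapping the anchor gene tail for NATs)."""
    n_lnc = (config.n_lnc_sequence_conserved + config.n_lnc_positional_only
             + config.n_lnc_private)
    if n_lnc:
        step = config.genes_per_genome // (n_lnc + 1)
        if step < 2:
            raise SizingError(
                f"{config.genes_per_genome} genes cannot hold {n_lnc} planted "
                "lncRNAs (need >= 2 gene slots per lncRNA)")
    lineage_names = [name for name, _ in config.lineages]
    planted: list[PlantedLnc] = []
    class_plan = (["sequence_conserved"] * config.n_lnc_sequence_conserved
                  + ["positional_only"] * config.n_lnc_positional_only
                  + ["private"] * config.n_lnc_private)
    seq_cat_cycle = ["LINC", "GATU", "NAT"]
    div_cat_cycle = [("LINC", "upstream"), ("LINC", "downstream"),
                     ("GATU", "upstream"), ("GATU", "downstream")]
    counters = {"sequence_conserved": 0, "positional_only": 0, "private": 0}
    for k, cls in enumerate(class_plan):
        anchor = (k + 1) * step
        i = counters[cls]
        counters[cls] += 1
        if cls == "sequence_conserved":
            category = seq_cat_cycle[i % 3]
            direction = "antisense" if category == "NAT" else \
                ("upstream" if i % 2 == 0 else "downstream")
            lineages = list(lineage_names)
        else:
            category, direction = div_cat_cycle[i % 4]
            lineages = (list(lineage_names) if cls == "positional_only"
                        else [lineage_names[i % len(lineage_names)]])
        planted.append(PlantedLnc(
            truth_id=f"lnc_{cls[:3]}_{i:03d}", conservation_class=cls,
            category=category, relative_direction=direction,
            anchor_gene_index=anchor, lineages=lineages,
            strand="+",  # refined below per placement
        ))
    # spacer lengths; spacers that will hold a planted lncRNA are widened so
    # the locus fits and the anchor stays the nearest gene
    spacer_lengths = np.maximum(
        rng.exponential(config.intergenic_mean_bp,
                        size=config.genes_per_genome + 1).astype(int), 300)
    gap_of = {"LINC": config.linc_gap_bp, "GATU": config.gatu_gap_bp}
    by_spacer: dict[int, tuple[PlantedLnc, str]] = {}
    for p in planted:
        # upstream/downstream in gene reading orientation; anchor strands are
        # assigned deterministically below (gene i strand: + if i even)
        anchor_strand = "+" if p.anchor_gene_index % 2 == 0 else "-"
        if p.category == "NAT":
            # locus overlaps the anchor gene tail; the overhang into the
            # adjacent spacer is carved as its own segment so the whole NAT
            # locus evolves at the class rate
            overhang = config.lnc_length_bp - config.nat_overlap_bp
            if anchor_strand == "+":
                spacer_idx, mode = p.anchor_gene_index + 1, "nat_head"
            else:
                spacer_idx, mode = p.anchor_gene_index, "nat_tail"
            need = overhang + 300
        else:
            left_side = (p.relative_direction == "upstream") == (anchor_strand == "+")
            spacer_idx = p.anchor_gene_index if left_side else p.anchor_gene_index + 1
            mode = "full"
            need = 2 * gap_of[p.category] + config.lnc_length_bp + 400
        if spacer_idx in by_spacer:
            raise SizingError("two planted lncRNAs collide in one intergenic "
                              "interval; increase genes_per_genome")
        by_spacer[spacer_idx] = (p, mode)
        spacer_lengths[spacer_idx] = max(spacer_lengths[spacer_idx], need)
    segments: list[_Segment] = []
    for g in range(config.genes_per_genome):
        segments.extend(_spacer_segments(g, spacer_lengths[g], by_spacer,
                                         config))
        segments.append(_Segment("gene", config.gene_length_bp, gene_index=g))
    segments.extend(_spacer_segments(config.genes_per_genome,
                                     spacer_lengths[config.genes_per_genome],
                                     by_spacer, config))
    return segments, planted


def _spacer_segments(spacer_idx: int, length: int,
                     by_spacer: dict[int, tuple[PlantedLnc, str]],
                     config: SimConfig) -> list[_Segment]:
    """Split one intergenic spacer into plain spacer pieces and, when a
    lncRNA is planted there, its locus segment: at the configured gap from
    the adjacent anchor gene ("full"), or the overhang of a NAT locus at the
    spacer edge touching the anchor ("nat_head"/"nat_tail")."""
    entry = by_spacer.get(spacer_idx)
    if entry is None:
        return [_Segment("spacer", int(length))]
    p, mode = entry
    lnc_len = config.lnc_length_bp
    if mode == "nat_head":
        overhang = lnc_len - config.nat_overlap_bp
        segs = [_Segment("lnc", overhang, truth_id=p.truth_id),
                _Segment("spacer", int(length) - overhang)]
    elif mode == "nat_tail":
        overhang = lnc_len - config.nat_overlap_bp
        segs = [_Segment("spacer", int(length) - overhang),
                _Segment("lnc", overhang, truth_id=p.truth_id)]
    else:
        gap = config.linc_gap_bp if p.category == "LINC" else config.gatu_gap_bp
        anchor_strand = "+" if p.anchor_gene_index % 2 == 0 else "-"
        left_side = (p.relative_direction == "upstream") == (anchor_strand == "+")
        rest = int(length) - gap - lnc_len
        if left_side:
            # anchor gene sits to the right of this spacer: [rest][lnc][gap]
            segs = [_Segment("spacer", rest),
                    _Segment("lnc", lnc_len, truth_id=p.truth_id),
                    _Segment("spacer", gap)]
        else:
            # anchor gene to the left: [gap][lnc][rest]
            segs = [_Segment("spacer", gap),
                    _Segment("lnc", lnc_len, truth_id=p.truth_id),
                    _Segment("spacer", rest)]
    if any(s.length <= 0 for s in segs):
        raise SizingError("intergenic interval too small for the planted "
                          "lncRNA; increase intergenic_mean_bp")
    return segs


def generate_phylogenomic_truth(config: SimConfig) -> SimResult:
    """Draw the ancestral genome once and derive every species genome,
    annotation and transcript set plus the recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    if config.gene_length_bp < 120:
        raise SizingError("gene_length_bp must be >= 120 to hold an ORF")
    segments, planted = _plan_layout(config, rng)
    truth_by_id = {p.truth_id: p for p in planted}

    # ancestral sequences per segment
    ancestral: list[str] = []
    for seg in segments:
        if seg.role == "gene":
            ancestral.append(_random_coding_gene(seg.length, rng))
        elif seg.role == "lnc":
            ancestral.append(_random_lnc(seg.length, rng))
        else:
            ancestral.append(_random_seq(seg.length, rng))

    # per-segment divergence rate at the lineage level
    def lineage_rate(seg: _Segment) -> float:
        if seg.role == "gene":
            return config.cds_divergence
        if seg.role == "lnc":
            cls = truth_by_id[seg.truth_id].conservation_class
            return (config.cds_divergence if cls == "sequence_conserved"
                    else config.lnc_divergence)
        return config.lnc_divergence  # intergenic, intron-like

    # two-level divergence: lineage ancestors, then species
    genomes: dict[str, dict[str, str]] = {}
    for lineage_name, n_species in config.lineages:
        lineage_seqs = [mutate_sequence(a, lineage_rate(seg), rng)
                        for seg, a in zip(segments, ancestral)]
        for i in range(n_species):
            sp = f"{lineage_name[:4]}_sp{i + 1}"
            parts = [mutate_sequence(ls, lineage_rate(seg)
                                     * config.within_lineage_scale, rng)
                     for seg, ls in zip(segments, lineage_seqs)]
            genomes[sp] = {"chr1": "".join(parts)}

    # coordinates are shared (substitution-only model)
    coords: list[tuple[_Segment, int, int]] = []
    pos = 0
    for seg in segments:
        coords.append((seg, pos, pos + seg.length))
        pos += seg.length
    chrom_len = pos
    gene_coords = {seg.gene_index: (start, end)
                   for seg, start, end in coords if seg.role == "gene"}
    lnc_coords = {seg.truth_id: (start, end)
                  for seg, start, end in coords if seg.role == "lnc"}

    # NAT loci overlap the anchor gene tail (opposite strand)
    for p in planted:
        if p.category == "NAT":
            g_start, g_end = gene_coords[p.anchor_gene_index]
            anchor_strand = "+" if p.anchor_gene_index % 2 == 0 else "-"
            if anchor_strand == "+":
                start = g_end - config.nat_overlap_bp
                end = start + config.lnc_length_bp
            else:
                end = g_start + config.nat_overlap_bp
                start = end - config.lnc_length_bp
            if start < 0 or end > chrom_len:
                raise SizingError("NAT locus outside chromosome bounds")
            p.start, p.end = start, end
            p.strand = "-" if anchor_strand == "+" else "+"
        else:
            p.start, p.end = lnc_coords[p.truth_id]
            p.strand = "+"
        p.chrom_id = "chr1"

    # annotations: protein-coding genes, deterministic alternating strands
    annotations: dict[str, GenomeAnnotation] = {}
    for sp in config.species_ids:
        genes = [GeneFeature(gene_id=f"{sp}.g{gi:04d}", chrom_id="chr1",
                             start=start, end=end,
                             strand="+" if gi % 2 == 0 else "-")
                 for gi, (start, end) in sorted(gene_coords.items())]
        annotations[sp] = GenomeAnnotation(sp, [("chr1", chrom_len)], genes)

    # transcripts: planted lncRNAs of carrier species + a coding sample
    species_to_lineage = config.species_to_lineage
    coding_sample = _coding_sample_indices(config)
    transcripts: dict[str, dict[str, str]] = {}
    for sp in config.species_ids:
        lineage = species_to_lineage[sp]
        txs: dict[str, str] = {}
        for p in planted:
            if lineage not in p.lineages:
                continue
            seq = genomes[sp]["chr1"][p.start:p.end]
            txs[f"{sp}|{p.truth_id}"] = revcomp(seq) if p.strand == "-" else seq
        for gi in coding_sample:
            start, end = gene_coords[gi]
            seq = genomes[sp]["chr1"][start:end]
            strand = "+" if gi % 2 == 0 else "-"
            txs[f"{sp}|g{gi:04d}"] = revcomp(seq) if strand == "-" else seq
        transcripts[sp] = txs

    return SimResult(config, genomes, annotations, transcripts,
                     SyntheticTruth(planted))


def _coding_sample_indices(config: SimConfig) -> list[int]:
    """Gene indices whose mRNAs are included in the transcript sets; chosen
    away from planted anchors so coding transcripts never sit in a planted
    neighbourhood."""
    n_lnc = (config.n_lnc_sequence_conserved + config.n_lnc_positional_only
             + config.n_lnc_private)
    anchors = set()
    if n_lnc:
        step = config.genes_per_genome // (n_lnc + 1)
        anchors = {(k + 1) * step for k in range(n_lnc)}
        anchors |= {a + 1 for a in anchors} | {a - 1 for a in anchors}
    out = []
    for gi in range(config.genes_per_genome):
        if gi in anchors:
            continue
        out.append(gi)
        if len(out) >= config.n_coding_transcripts:
            break
    return out


# --- file output -------------------------------------------------------------

def write_fixture(result: SimResult, outdir) -> dict[str, dict[str, str]]:
    """Write the standard file layout (per-species genome FASTA, GFF3 and
    transcript FASTA, plus truth TSV and config YAML); returns the path map."""
    import yaml
    from pathlib import Path

    from .io import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, str]] = {}
    for sp in result.config.species_ids:
        genome_path = outdir / f"{sp}.genome.fa"
        gff_path = outdir / f"{sp}.gff3"
        tx_path = outdir / f"{sp}.transcripts.fa"
        write_fasta(result.genomes[sp], genome_path)
        write_gff3(result.annotations[sp], gff_path)
        write_fasta(result.transcripts[sp], tx_path)
        paths[sp] = {"genome": str(genome_path), "annotation": str(gff_path),
                     "transcripts": str(tx_path)}
    lines = ["truth_id\tconservation_class\tcategory\trelative_direction\t"
             "anchor_gene_index\tlineages\tchrom\tstart\tend\tstrand"]
    for p in result.truth.lncs:
        lines.append("\t".join([
            p.truth_id, p.conservation_class, p.category, p.relative_direction,
            str(p.anchor_gene_index), ",".join(p.lineages), p.chrom_id,
            str(p.start), str(p.end), p.strand]))
    (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")
    cfg = asdict(result.config)
    cfg["lineages"] = [list(t) for t in cfg["lineages"]]
    (outdir / "sim_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
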