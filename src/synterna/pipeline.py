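"""End-to-end orchestration: files in, conservation report out.

Stage order: candidate detection -> localization -> categorization ->
cross-species homology clustering (per identity cutoff) -> lineage labels ->
gene-anchor synteny -> positional-conservation calls -> telomere statistics
-> secondary-structure classification of the positionally conserved set.
Every stage writes its artifact as plain TSV/JSON; a fixed config and input
set reproduces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import PairwiseHit, Scoring, SeedParams, SequenceDatabase
from .annotate import (GenomeAnnotation, LncCandidate, LocationRejection,
                       flag_mirna_precursor, is_lnc_candidate,
                       locate_transcript, make_candidate, scan_orfs)
from .cluster import HomologyCluster, LineageConfig, cluster_transcripts
from .io import (candidates_to_frame, read_fasta, read_gff3,
                 write_candidates_bed, write_hits_outfmt6, write_vienna)
from .positional import (ConservationSummary, PositionalCall, TelomereReport,
                         positional_call, summarize_positional,
                         telomere_proximity)
from .structure import FoldResult, classify_stability, fold_energy
from .synteny import chain_anchors, find_anchors

logger = logging.getLogger("synterna")


@dataclass
class SpeciesInput:
    species_id: str
    lineage: str
    genome: str
    annotation: str
    transcripts: str


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    output_dir: str
    identity_cutoffs: list[float] = field(default_factory=lambda: [10.0, 20.0, 50.0])
    classify_threshold_bp: int = 500
    min_species_transcribed: int = 2
    outgroup_db: str | None = None
    mirna_db: str | None = None
    evalue_cutoff: float = 1e-10
    mcl_inflation: float = 1.5
    max_gap_genes: int = 20
    min_anchors: int = 4
    telomere_threshold_bp: int = 2_500_000
    max_fold_length: int = 5000
    seed: int = 0
    scoring: Scoring = field(default_factory=Scoring)
    seed_params: SeedParams = field(default_factory=SeedParams)

    def validate(self) -> None:
        if list(self.identity_cutoffs) != sorted(self.identity_cutoffs):
            raise ValueError("identity_cutoffs must be strictly increasing")
        if len(set(self.identity_cutoffs)) != len(self.identity_cutoffs):
            raise ValueError("identity_cutoffs must be strictly increasing")
        for sp in self.species:
            for attr in ("genome", "annotation", "transcripts"):
                p = Path(getattr(sp, attr))
                if not p.exists():
                    raise FileNotFoundError(
                        f"species {sp.species_id}: missing {attr} file {p}")

    @property
    def lineage_config(self) -> LineageConfig:
        return LineageConfig(
            {sp.species_id: sp.lineage for sp in self.species},
            min_species_transcribed=self.min_species_transcribed,
            outgroup_db=self.outgroup_db)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesInput(**sp) for sp in raw.pop("species")]
        return cls(species=species, **raw)


@dataclass
class RunReport:
    stage_counts: dict[str, int]
    summary: ConservationSummary
    telomere: TelomereReport
    clusters: dict[float, list[HomologyCluster]]
    candidates: dict[str, list[LncCandidate]]
    folds: list[FoldResult]
    provenance: dict[str, str]


def _config_hash(config: RunConfig) -> str:
    blob = repr((sorted((s.species_id, s.lineage) for s in config.species),
                 config.identity_cutoffs, config.classify_threshold_bp,
                 config.min_species_transcribed, config.evalue_cutoff,
                 config.mcl_inflation, config.max_gap_genes,
                 config.min_anchors, config.telomere_threshold_bp,
                 config.seed))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def detect_candidates(species: SpeciesInput, annotation: GenomeAnnotation,
                      transcripts: dict[str, str], genome: dict[str, str],
                      config: RunConfig
                      ) -> tuple[list[LncCandidate], dict[str, str]]:
    """Filter transcripts by the lncRNA rule, locate the survivors on their
    own genome, and categorize the located ones.  Returns the candidate list
    plus a {transcript_id: rejection reason} map."""
    db = SequenceDatabase(genome, config.scoring, config.seed_params)
    candidates = []
    rejected: dict[str, str] = {}
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        reports = scan_orfs(seq, tid)
        if not is_lnc_candidate(seq, reports):
            rejected[tid] = "orf_or_length"
            continue
        hits = db.search(seq, query_id=tid,
                         evalue_threshold=config.evalue_cutoff)
        located = locate_transcript(tid, len(seq), hits)
        if isinstance(located, LocationRejection):
            rejected[tid] = located.reason
            continue
        candidates.append(make_candidate(
            tid, species.species_id, seq, located, annotation,
            config.classify_threshold_bp, orf_reports=reports))
    return candidates, rejected


def cross_species_hits(candidate_seqs: dict[str, dict[str, str]],
                       config: RunConfig) -> list[PairwiseHit]:
    """All-vs-all HSPs between candidate transcripts of different species."""
    hits: list[PairwiseHit] = []
    species = sorted(candidate_seqs)
    dbs = {sp: SequenceDatabase(candidate_seqs[sp], config.scoring,
                                config.seed_params)
           for sp in species}
    for sp_q in species:
        for sp_s in species:
            if sp_q == sp_s:
                continue
            db = dbs[sp_s]
            for tid in sorted(candidate_seqs[sp_q]):
                for hit in db.search(candidate_seqs[sp_q][tid], query_id=tid,
                                     evalue_threshold=config.evalue_cutoff):
                    hits.append(hit)
    return hits


def gene_orthologs(annot_a: GenomeAnnotation, genome_a: dict[str, str],
                   annot_b: GenomeAnnotation, genome_b: dict[str, str],
                   config: RunConfig,
                   min_identity_pct: float = 50.0
                   ) -> list[tuple[str, str, float]]:
    """Reciprocal-best-hit protein-coding gene pairs between two genomes,
    from nucleotide alignment of the gene bodies."""
    def gene_seqs(annot, genome):
        out = {}
        for g in annot.coding_genes():
            seq = genome[g.chrom_id][g.start:g.end]
            out[g.gene_id] = seq
        return out

    seqs_a = gene_seqs(annot_a, genome_a)
    seqs_b = gene_seqs(annot_b, genome_b)
    db_b = SequenceDatabase(seqs_b, config.scoring, config.seed_params)
    db_a = SequenceDatabase(seqs_a, config.scoring, config.seed_params)
    best_ab: dict[str, tuple[str, float]] = {}
    best_ba: dict[str, tuple[str, float]] = {}
    for ga in sorted(seqs_a):
        hits = db_b.search(seqs_a[ga], query_id=ga,
                           evalue_threshold=config.evalue_cutoff)
        hits = [h for h in hits if h.identity_pct >= min_identity_pct]
        if hits:
            best_ab[ga] = (hits[0].subject_id, float(hits[0].score))
    for gb in sorted(seqs_b):
        hits = db_a.search(seqs_b[gb], query_id=gb,
                           evalue_threshold=config.evalue_cutoff)
        hits = [h for h in hits if h.identity_pct >= min_identity_pct]
        if hits:
            best_ba[gb] = (hits[0].subject_id, float(hits[0].score))
    pairs = []
    for ga, (gb, score) in sorted(best_ab.items()):
        back = best_ba.get(gb)
        if back is not None and back[0] == ga:
            pairs.append((ga, gb, score))
    return pairs


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    lineage_config = config.lineage_config

    # --- load inputs
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    transcripts: dict[str, dict[str, str]] = {}
    for sp in config.species:
        genomes[sp.species_id] = read_fasta(sp.genome)
        annotations[sp.species_id] = read_gff3(sp.annotation, sp.species_id)
        transcripts[sp.species_id] = read_fasta(sp.transcripts)
    stage_counts["species"] = len(config.species)
    stage_counts["transcripts_in"] = sum(len(t) for t in transcripts.values())

    # --- stage 1-3: candidates per species
    candidates: dict[str, list[LncCandidate]] = {}
    for sp in config.species:
        cands, rejected = detect_candidates(
            sp, annotations[sp.species_id], transcripts[sp.species_id],
            genomes[sp.species_id], config)
        candidates[sp.species_id] = cands
        logger.info("%s: %d lncRNA candidates (%d rejected)",
                    sp.species_id, len(cands), len(rejected))
    all_candidates = [c for cs in candidates.values() for c in cs]
    stage_counts["lnc_candidates"] = len(all_candidates)
    if config.mirna_db:
        mirna_db = SequenceDatabase(read_fasta(config.mirna_db),
                                    config.scoring, config.seed_params)
        for c in all_candidates:
            seq = transcripts[c.species_id][c.transcript_id]
            if len(seq) > config.max_fold_length:
                continue
            mfe = fold_energy(seq, sequence_id=c.transcript_id,
                              max_length=config.max_fold_length).mfe_kcal_mol
            c.mirna_precursor = flag_mirna_precursor(seq, mirna_db, mfe)
        stage_counts["mirna_precursors"] = sum(
            c.mirna_precursor for c in all_candidates)
    frame = candidates_to_frame(all_candidates)
    frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    for sp_id, cands in candidates.items():
        write_candidates_bed(cands, outdir / f"{sp_id}.candidates.bed")

    # --- stage 4: homology clustering per cutoff
    candidate_seqs = {
        sp.species_id: {c.transcript_id: transcripts[sp.species_id][c.transcript_id]
                        for c in candidates[sp.species_id]}
        for sp in config.species}
    hits = cross_species_hits(candidate_seqs, config)
    stage_counts["cross_species_hits"] = len(hits)
    write_hits_outfmt6(hits, outdir / "hits.tsv")
    species_of = {c.transcript_id: c.species_id for c in all_candidates}
    outgroup_hit_ids = _outgroup_screen(candidate_seqs, config)
    clusters = cluster_transcripts(hits, species_of, config.identity_cutoffs,
                                   lineage_config, outgroup_hit_ids,
                                   inflation=config.mcl_inflation,
                                   evalue_cutoff=config.evalue_cutoff)
    _write_clusters(clusters, outdir / "clusters.tsv")
    top_cutoff = max(config.identity_cutoffs) if config.identity_cutoffs else None
    lineage_specific = [cl for cl in clusters.get(top_cutoff, [])
                        if cl.lineage_label in lineage_config.lineages] \
        if top_cutoff is not None else []
    stage_counts["lineage_specific_clusters"] = len(lineage_specific)

    # --- stage 5: synteny blocks for the needed species pairs
    by_id = {c.transcript_id: c for c in all_candidates}
    needed_pairs = set()
    for cl in lineage_specific:
        src_species, _ = cl.representative
        src_lineage = lineage_config.species_to_lineage[src_species]
        for sp in config.species:
            if sp.lineage != src_lineage:
                needed_pairs.add((src_species, sp.species_id))
    blocks = {}
    for src, tgt in sorted(needed_pairs):
        pairs = gene_orthologs(annotations[src], genomes[src],
                               annotations[tgt], genomes[tgt], config)
        anchors = find_anchors(annotations[src], annotations[tgt], pairs)
        blocks[(src, tgt)] = chain_anchors(anchors, config.max_gap_genes,
                                           config.min_anchors)
    stage_counts["synteny_pairs"] = len(blocks)

    # --- stage 6: positional calls
    calls: list[PositionalCall] = []
    lineage_of_lnc: dict[str, str] = {}
    for cl in lineage_specific:
        src_species, rep_id = cl.representative
        lineage_of_lnc[rep_id] = cl.lineage_label
        rep = by_id[rep_id]
        for sp in config.species:
            if sp.lineage == cl.lineage_label:
                continue
            tgt = sp.species_id
            calls.append(positional_call(
                rep, annotations[src_species], annotations[tgt],
                blocks.get((src_species, tgt), []), candidates[tgt]))
    stage_counts["positional_calls"] = len(calls)
    summary = summarize_positional(calls, lineage_of_lnc)
    _write_calls(calls, outdir / "positional_calls.tsv")

    # --- stage 7: telomere proximity of positionally conserved loci
    telomere_loci = []
    for lnc_id in summary.dual_class_loci:
        c = by_id[lnc_id]
        telomere_loci.append((lnc_id, c.location.chrom_id,
                              c.location.start, c.location.end))
    chrom_lengths = {}
    for annot in annotations.values():
        chrom_lengths.update(dict(annot.chromosomes))
    telomere = telomere_proximity(telomere_loci, chrom_lengths,
                                  config.telomere_threshold_bp)
    _write_telomere(telomere, telomere_loci, outdir)

    # --- stage 8: structure classification of the conserved set
    folds: list[FoldResult] = []
    vienna_rows = []
    for lnc_id in summary.dual_class_loci:
        c = by_id[lnc_id]
        seq = transcripts[c.species_id][lnc_id]
        if len(seq) > config.max_fold_length:
            continue
        fr = fold_energy(seq, sequence_id=lnc_id,
                         max_length=config.max_fold_length)
        fr.stability_class = classify_stability(fr.mfe_kcal_mol,
                                                "lncrna_structure")
        folds.append(fr)
        vienna_rows.append((lnc_id, seq.replace("T", "U"), fr))
    write_vienna(vienna_rows, outdir / "structures.vienna")
    stage_counts["folded"] = len(folds)

    provenance = {"config_hash": _config_hash(config), "version": __version__}
    report = RunReport(stage_counts, summary, telomere, clusters, candidates,
                       folds, provenance)
    (outdir / "report.json").write_text(report_to_json(report))
    return report


def _outgroup_screen(candidate_seqs: dict[str, dict[str, str]],
                     config: RunConfig) -> set[str]:
    if not config.outgroup_db:
        return set()
    out_db = SequenceDatabase(read_fasta(config.outgroup_db), config.scoring,
                              config.seed_params)
    top_cutoff = max(config.identity_cutoffs) if config.identity_cutoffs else 0.0
    flagged = set()
    for sp in sorted(candidate_seqs):
        for tid in sorted(candidate_seqs[sp]):
            hits = out_db.search(candidate_seqs[sp][tid], query_id=tid,
                                 evalue_threshold=config.evalue_cutoff)
            if any(h.identity_pct >= top_cutoff for h in hits):
                flagged.add(tid)
    return flagged


def _write_clusters(clusters: dict[float, list[HomologyCluster]], path) -> None:
    lines = ["cluster_id\tcutoff_pct\tlineage_label\tn_members\tmembers"]
    for cutoff in sorted(clusters):
        for cl in clusters[cutoff]:
            members = ",".join(f"{sp}:{tid}" for sp, tid in cl.members)
            lines.append(f"{cl.cluster_id}\t{cutoff:g}\t{cl.lineage_label}\t"
                         f"{len(cl.members)}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_calls(calls: list[PositionalCall], path) -> None:
    lines = ["lnc_id\tsource_species\ttarget_species\tstatus\t"
             "relative_direction\tmatched_lnc_id\tanchor_gene_id"]
    for c in calls:
        lines.append("\t".join([
            c.lnc_id, c.source_species, c.target_species, c.status,
            c.relative_direction or ".", c.matched_lnc_id or ".",
            c.anchor_gene_id or "."]))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_telomere(report: TelomereReport,
                    loci: list[tuple[str, str, int, int]],
                    outdir: Path) -> None:
    coords = {lnc_id: (start, end) for lnc_id, _, start, end in loci}
    lines = ["lnc_id\tchrom\tdistance_to_nearest_end_bp\twithin_threshold"]
    bed = []
    for lnc_id, chrom, dist in report.loci:
        within = dist <= report.threshold_bp
        lines.append(f"{lnc_id}\t{chrom}\t{dist}\t{str(within).lower()}")
        if within:
            start, end = coords[lnc_id]
            bed.append(f"{chrom}\t{start}\t{end}\t{lnc_id}")
    Path(outdir / "telomere.tsv").write_text("\n".join(lines) + "\n")
    Path(outdir / "telomere_within.bed").write_text(
        "\n".join(bed) + ("\n" if bed else ""))


def report_to_json(report: RunReport) -> str:
    payload = {
        "stage_counts": report.stage_counts,
        "provenance": report.provenance,
        "per_lineage": [{
            "lineage": s.lineage,
            "n_lineage_specific": s.n_lineage_specific,
            "n_positionally_conserved": s.n_positionally_conserved,
            "pct_positional": (None if s.n_lineage_specific == 0
                               else round(s.pct_positional, 4)),
        } for s in report.summary.per_lineage],
        "dual_class_loci": report.summary.dual_class_loci,
        "telomere": {
            "threshold_bp": report.telomere.threshold_bp,
            "n_within": report.telomere.n_within,
            "n_total": report.telomere.n_total,
            "fraction_within": (None if report.telomere.n_total == 0
                                else round(report.telomere.fraction_within, 6)),
        },
        "folds": [{
            "id": f.sequence_id, "mfe_kcal_mol": f.mfe_kcal_mol,
            "pair_count": f.pair_count, "stability_class": f.stability_class,
        } for f in report.folds],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
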