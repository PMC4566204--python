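"""lncRNA candidate detection and categorization.

A long non-coding RNA candidate is a transcript longer than 200 nt whose
longest open reading frame (any of the six frames, strict ATG start) is
shorter than 100 amino acids.  Located candidates are categorized against the
protein-coding annotation:

* NAT  - the transcriptional unit overlaps a protein-coding gene on the
         opposite strand (natural antisense transcript);
* GATU - gene-associated transcriptional unit, within 500 bp of a gene;
* LINC - long intergenic ncRNA, >= 500 bp away from the nearest gene,
         regardless of strand.

All coordinates are 0-based half-open internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .align import PairwiseHit, revcomp

_STOPS = {"TAA", "TAG", "TGA"}

LNC_MIN_LENGTH_NT = 200
LNC_MAX_ORF_AA = 100  # exclusive: ORF must be *smaller* than 100 aa
DEFAULT_CLASSIFY_THRESHOLD_BP = 500


@dataclass
class GeneFeature:
    gene_id: str
    chrom_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    kind: str = "protein_coding"  # or "lnc_annotation"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval "
                             f"[{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    species_id: str
    chromosomes: list[tuple[str, int]]
    genes: list[GeneFeature]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom_id not in lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom_id}")
            if g.end > lengths[g.chrom_id]:
                raise ValueError(f"gene {g.gene_id}: extends past end of {g.chrom_id}")

    def chrom_length(self, chrom_id: str) -> int:
        return dict(self.chromosomes)[chrom_id]

    def coding_genes(self, chrom_id: str | None = None) -> list[GeneFeature]:
        return [g for g in self.genes
                if g.kind == "protein_coding"
                and (chrom_id is None or g.chrom_id == chrom_id)]


@dataclass
class OrfReport:
    transcript_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    orf_start_nt: int  # 0-based offset of the ATG on the reported strand
    orf_length_aa: int  # stop codon excluded


@dataclass
class TranscriptLocation:
    chrom_id: str
    start: int
    end: int
    strand: str


@dataclass
class LocationRejection:
    reason: str  # multi_hsp | low_coverage | no_hit


@dataclass
class LncCandidate:
    transcript_id: str
    species_id: str
    location: TranscriptLocation
    category: str  # LINC | GATU | NAT (or "unclassifiable")
    nearest_gene_id: str | None
    distance_bp: int
    transcript_length_nt: int
    max_orf_aa: int
    mirna_precursor: bool = False
    relative_direction: str = field(default="")


def _scan_strand(seq: str, sign: int, transcript_id: str) -> list[OrfReport]:
    n = len(seq)
    reports = []
    for offset in range(3):
        pos = offset
        while pos + 3 <= n:
            if seq[pos:pos + 3] == "ATG":
                aa = 0
                stop_found = False
                p = pos + 3
                while p + 3 <= n:
                    codon = seq[p:p + 3]
                    if codon in _STOPS:
                        stop_found = True
                        break
                    aa += 1
                    p += 3
                # ATG itself encodes Met; count it
                length_aa = aa + 1
                reports.append(OrfReport(transcript_id, sign * (offset + 1),
                                         pos, length_aa))
                # skip to past this ORF's end to report only maximal ORFs
                pos = (p + 3) if stop_found else (pos + 3)
                if not stop_found:
                    break
            else:
                pos += 3
    return reports


def scan_orfs(transcript_seq: str, transcript_id: str = "transcript") -> list[OrfReport]:
    """Maximal ORFs (strict ATG start, first in-frame stop or sequence end) in
    all six frames; amino-acid lengths exclude the stop codon."""
    seq = transcript_seq.upper().replace("U", "T")
    if any(b not in "ACGTN" for b in seq):
        raise ValueError("scan_orfs: sequence contains non-ACGTN characters")
    if not seq:
        return []
    return (_scan_strand(seq, +1, transcript_id)
            + _scan_strand(revcomp(seq), -1, transcript_id))


def max_orf_aa(orf_reports: list[OrfReport]) -> int:
    return max((r.orf_length_aa for r in orf_reports), default=0)


def is_lnc_candidate(transcript_seq: str, orf_reports: list[OrfReport]) -> bool:
    """Length >= 200 nt and every ORF < 100 amino acids."""
    return (len(transcript_seq) >= LNC_MIN_LENGTH_NT
            and max_orf_aa(orf_reports) < LNC_MAX_ORF_AA)


def locate_transcript(transcript_id: str, transcript_length: int,
                      hits: list[PairwiseHit],
                      min_query_coverage: float = 0.5
                      ) -> TranscriptLocation | LocationRejection:
    """Accept a genomic location only for a unique HSP covering >= 50% of the
    query; otherwise reject with a reason (multi_hsp | low_coverage | no_hit)."""
    if not hits:
        return LocationRejection("no_hit")
    if len(hits) > 1:
        return LocationRejection("multi_hsp")
    h = hits[0]
    if h.aln_span_query < min_query_coverage * transcript_length:
        return LocationRejection("low_coverage")
    return TranscriptLocation(h.subject_id, h.sstart, h.send, h.strand)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 when overlapping."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def relative_direction(tu_start: int, tu_end: int, tu_strand: str,
                       gene: GeneFeature) -> str:
    """Direction of a transcriptional unit relative to a gene, in the gene's
    own reading orientation: upstream / downstream / antisense / overlapping."""
    if _gap(tu_start, tu_end, gene.start, gene.end) == 0:
        return "antisense" if tu_strand != gene.strand else "overlapping"
    left_of_gene = (tu_start + tu_end) / 2 < gene.start
    if gene.strand == "+":
        return "upstream" if left_of_gene else "downstream"
    return "downstream" if left_of_gene else "upstream"


def classify_lnc(location: TranscriptLocation, annotation: GenomeAnnotation,
                 threshold_bp: int = DEFAULT_CLASSIFY_THRESHOLD_BP
                 ) -> tuple[str, str | None, int]:
    """Assign (category, nearest_gene_id, distance_bp) for a located TU.

    Precedence NAT > GATU > LINC: an antisense overlap is a NAT even though
    its distance is 0.  Distance exactly `threshold_bp` is a LINC (the
    intergenic rule is stated with >=).  Nearest-gene ties break on gene_id.
    """
    genes = annotation.coding_genes(location.chrom_id)
    if not genes:
        return "unclassifiable", None, -1
    nearest = min(genes, key=lambda g: (_gap(location.start, location.end,
                                             g.start, g.end), g.gene_id))
    distance = _gap(location.start, location.end, nearest.start, nearest.end)
    # NAT: overlapping a gene on the opposite strand (any overlapping gene)
    for g in genes:
        if (_gap(location.start, location.end, g.start, g.end) == 0
                and g.strand != location.strand):
            return "NAT", g.gene_id, 0
    if distance < threshold_bp:
        return "GATU", nearest.gene_id, distance
    return "LINC", nearest.gene_id, distance


def make_candidate(transcript_id: str, species_id: str, seq: str,
                   location: TranscriptLocation, annotation: GenomeAnnotation,
                   threshold_bp: int = DEFAULT_CLASSIFY_THRESHOLD_BP,
                   orf_reports: list[OrfReport] | None = None) -> LncCandidate:
    reports = orf_reports if orf_reports is not None else scan_orfs(seq, transcript_id)
    category, gene_id, distance = classify_lnc(location, annotation, threshold_bp)
    direction = ""
    if gene_id is not None:
        gene = next(g for g in annotation.genes if g.gene_id == gene_id)
        direction = relative_direction(location.start, location.end,
                                       location.strand, gene)
    return LncCandidate(
        transcript_id=transcript_id,
        species_id=species_id,
        location=location,
        category=category,
        nearest_gene_id=gene_id,
        distance_bp=distance,
        transcript_length_nt=len(seq),
        max_orf_aa=max_orf_aa(reports),
        relative_direction=direction,
    )


def flag_mirna_precursor(transcript_seq: str, mirna_db, fold_mfe: float,
                         min_identity_pct: float = 90.0,
                         min_ref_coverage: float = 0.9,
                         evalue_threshold: float = 1e-3) -> bool:
    """True iff the transcript matches a reference miRNA (identity >= 90% over
    >= 90% of the reference length) AND the fold MFE lies in [-80, -30].

    `mirna_db` is a SequenceDatabase over mature/hairpin reference sequences
    (may be None or empty -> always False).
    """
    if mirna_db is None or not getattr(mirna_db, "sequences", None):
        return False
    if not (-80.0 <= fold_mfe <= -30.0):
        return False
    db = SequenceDatabaseView(mirna_db)
    for ref_id, ref_seq in sorted(db.sequences.items()):
        hit = _best_ref_hit(ref_seq, transcript_seq, mirna_db, ref_id,
                            evalue_threshold)
        if hit is None:
            continue
        # identity_pct is computed over the reference (query) length
        if (hit.identity_pct >= min_identity_pct
                and hit.aln_span_query >= min_ref_coverage * len(ref_seq)):
            return True
    return False


class SequenceDatabaseView:
    """Tiny adapter so flag_mirna_precursor accepts a SequenceDatabase or a
    plain {id: sequence} mapping."""

    def __init__(self, db):
        self.sequences = db.sequences if hasattr(db, "sequences") else dict(db)


def _best_ref_hit(ref_seq: str, transcript_seq: str, db, ref_id: str,
                  evalue_threshold: float):
    from .align import Scoring, pairwise_similarity
    scoring = getattr(db, "scoring", Scoring())
    return pairwise_similarity(ref_seq, transcript_seq, scoring,
                               query_id=ref_id, subject_id="transcript",
                               evalue_threshold=evalue_threshold,
                               both_strands=True)
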