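"""Readers and writers for the standard formats the pipeline exchanges.

FASTA goes through Biopython (60-column wrapped on output, ids validated for
uniqueness, sequences normalized to upper case).  GFF3 is read and written by
a small strict parser for the `gene`/`mRNA` subset the pipeline uses: 1-based
inclusive coordinates on disk, 0-based half-open in memory, and validation
errors that carry line numbers.  Tables are plain TSV via pandas.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneFeature, GenomeAnnotation, LncCandidate

_IUPAC = set("ACGTUNRYSWKMBDHV")


class FormatError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} mapping."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(f"{path}: record {rec.id!r} contains non-IUPAC "
                              f"characters {sorted(bad)}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq.upper()), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(Path(path)), "fasta")


def _parse_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key] = value
    return out


def read_gff3(path, species_id: str | None = None) -> GenomeAnnotation:
    """Parse gene features from GFF3 (1-based inclusive on disk -> 0-based
    half-open in memory).  Chromosome lengths come from ##sequence-region
    pragmas; genes on chromosomes without a pragma get an open-ended bound."""
    path = Path(path)
    chroms: dict[str, int] = {}
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chroms[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, "
                                  f"got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in ("gene", "ncRNA_gene"):
                continue
            attributes = _parse_attributes(attrs)
            if "ID" not in attributes:
                raise FormatError(f"{path}:{lineno}: gene feature without ID")
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -, "
                                  f"got {strand!r}")
            kind = ("lnc_annotation"
                    if ftype == "ncRNA_gene"
                    or attributes.get("biotype") == "lnc"
                    else "protein_coding")
            genes.append(GeneFeature(attributes["ID"], chrom,
                                     start_i - 1, end_i, strand, kind))
    for g in genes:
        if g.chrom_id not in chroms:
            chroms[g.chrom_id] = max((x.end for x in genes
                                      if x.chrom_id == g.chrom_id), default=0)
    return GenomeAnnotation(species_id or path.stem, sorted(chroms.items()),
                            genes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write genes (and a derived mRNA child per protein-coding gene) in a
    canonical byte-stable layout."""
    lines = ["##gff-version 3"]
    for chrom, length in annotation.chromosomes:
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for g in annotation.genes:
        ftype = "ncRNA_gene" if g.kind == "lnc_annotation" else "gene"
        biotype = "lnc" if g.kind == "lnc_annotation" else "protein_coding"
        lines.append("\t".join([
            g.chrom_id, "synterna", ftype, str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id};biotype={biotype}"]))
        if g.kind == "protein_coding":
            lines.append("\t".join([
                g.chrom_id, "synterna", "mRNA", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}.m1;Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidates_bed(candidates: list[LncCandidate], path) -> None:
    """BED6: name = transcript id, score = max ORF length (aa)."""
    rows = []
    for c in candidates:
        rows.append("\t".join([
            c.location.chrom_id, str(c.location.start), str(c.location.end),
            c.transcript_id, str(c.max_orf_aa), c.location.strand]))
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def candidates_to_frame(candidates: list[LncCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript_id": c.transcript_id,
        "species_id": c.species_id,
        "chrom": c.location.chrom_id,
        "start": c.location.start,
        "end": c.location.end,
        "strand": c.location.strand,
        "category": c.category,
        "nearest_gene_id": c.nearest_gene_id,
        "distance_bp": c.distance_bp,
        "relative_direction": c.relative_direction,
        "transcript_length_nt": c.transcript_length_nt,
        "max_orf_aa": c.max_orf_aa,
        "mirna_precursor": c.mirna_precursor,
    } for c in candidates])


def write_hits_outfmt6(hits, path) -> None:
    """Tab-separated 12-column hit table (BLAST outfmt-6 compatible,
    1-based inclusive coordinates, subject coordinates swapped on minus
    strand)."""
    lines = []
    for h in hits:
        if h.strand == "-":
            sstart, send = h.send, h.sstart + 1
        else:
            sstart, send = h.sstart + 1, h.send
        lines.append("\t".join(map(str, [
            h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.aln_len,
            h.mismatches, h.gap_opens, h.qstart + 1, h.qend, sstart, send,
            f"{h.evalue:.2e}", f"{h.bitscore:.1f}"])))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_vienna(fold_results, path) -> None:
    """Vienna text: header, sequence placeholder-free structure + energy."""
    lines = []
    for seq_id, seq, fr in fold_results:
        lines.append(f">{seq_id}")
        lines.append(seq)
        lines.append(f"{fr.structure} ({fr.mfe_kcal_mol:.2f})")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
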