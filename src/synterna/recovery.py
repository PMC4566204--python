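"""Scoring a pipeline run against the synthetic generator's recorded truth.

Planted transcript ids carry their truth id ("<species>|<truth_id>"), so a
run over a generated fixture can be scored exactly: sensitivity/precision of
the "sequence-diverged, positionally conserved" call for the planted
positional_only class, the false-positive rate over planted private loci,
and recovery of the sequence_conserved class as cross-lineage clusters at
the top identity cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

from .cluster import HomologyCluster, LineageConfig
from .pipeline import RunReport
from .simulate import SyntheticTruth


def truth_id_of(transcript_id: str) -> str | None:
    _, sep, rest = transcript_id.partition("|")
    return rest if sep else None


@dataclass
class RecoveryMetrics:
    positional_sensitivity: float
    positional_precision: float
    private_false_positive_rate: float
    sequence_conserved_cluster_sensitivity: float
    n_positional_truth: int
    n_private_truth: int
    n_sequence_conserved_truth: int
    n_predicted_positional: int


def evaluate_recovery(truth: SyntheticTruth, report: RunReport,
                      lineage_config: LineageConfig,
                      top_cutoff: float = 50.0) -> RecoveryMetrics:
    pos_truth = {p.truth_id for p in truth.by_class("positional_only")}
    priv_truth = {p.truth_id for p in truth.by_class("private")}
    seqc_truth = {p.truth_id for p in truth.by_class("sequence_conserved")}

    predicted = set()
    for lnc_id in report.summary.dual_class_loci:
        tid = truth_id_of(lnc_id)
        if tid is not None:
            predicted.add(tid)

    tp = len(predicted & pos_truth)
    sens = tp / len(pos_truth) if pos_truth else float("nan")
    prec = tp / len(predicted) if predicted else float("nan")
    fpr = (len(predicted & priv_truth) / len(priv_truth)
           if priv_truth else float("nan"))

    # sequence_conserved: does some top-cutoff cluster place the truth's
    # transcripts in >= 2 lineages?
    recovered_seqc = set()
    for cl in report.clusters.get(top_cutoff, []):
        lineages = set()
        truth_ids = set()
        for sp, transcript in cl.members:
            lineages.add(lineage_config.species_to_lineage[sp])
            tid = truth_id_of(transcript)
            if tid:
                truth_ids.add(tid)
        if len(lineages) >= 2:
            recovered_seqc |= truth_ids & seqc_truth
    seqc_sens = (len(recovered_seqc) / len(seqc_truth)
                 if seqc_truth else float("nan"))

    return RecoveryMetrics(
        positional_sensitivity=sens,
        positional_precision=prec,
        private_false_positive_rate=fpr,
        sequence_conserved_cluster_sensitivity=seqc_sens,
        n_positional_truth=len(pos_truth),
        n_private_truth=len(priv_truth),
        n_sequence_conserved_truth=len(seqc_truth),
        n_predicted_positional=len(predicted),
    )
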