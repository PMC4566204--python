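"""Cross-species homology clustering of transcripts.

Reciprocal-best-hit (RBH) graphs are built per identity cutoff and clustered
with Markov clustering (MCL): alternate expansion (matrix power) and inflation
(entrywise power + column renormalization) on the column-stochastic adjacency
with self-loops until the matrix converges; connected components of the final
support define the clusters.  Clusters are then labelled for lineage
specificity: a cluster is specific to lineage L when all members belong to L,
at least `min_species_transcribed` distinct species carry it, and no member
hits the outgroup database at the same cutoffs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import PairwiseHit


@dataclass
class LineageConfig:
    species_to_lineage: dict[str, str]
    min_species_transcribed: int = 2
    outgroup_db: str | None = None

    @property
    def lineages(self) -> list[str]:
        seen: list[str] = []
        for lin in self.species_to_lineage.values():
            if lin not in seen:
                seen.append(lin)
        return seen


@dataclass
class HomologyCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (species_id, transcript_id)
    cutoff_pct: float
    lineage_label: str = "unassigned"

    @property
    def transcript_ids(self) -> list[str]:
        return [t for _, t in self.members]

    @property
    def representative(self) -> tuple[str, str]:
        """Lowest transcript_id member; used to count loci once per cluster."""
        return min(self.members, key=lambda m: m[1])


def build_rbh_graph(all_hits: list[PairwiseHit], species_of: dict[str, str],
                    identity_cutoff_pct: float,
                    evalue_cutoff: float = 1e-10) -> nx.Graph:
    """Undirected RBH graph: an edge (a, b) requires b to be among a's
    best-scoring hits in b's species and vice versa, with both directions
    passing the identity and e-value cutoffs.  Ties keep all tied best hits;
    within-species pairs are ignored."""
    passing: dict[tuple[str, str], PairwiseHit] = {}
    best: dict[tuple[str, str], list[str]] = {}
    best_score: dict[tuple[str, str], float] = {}
    for h in all_hits:
        sp_q = species_of[h.query_id]
        sp_s = species_of[h.subject_id]
        if sp_q == sp_s or h.query_id == h.subject_id:
            continue
        if h.identity_pct < identity_cutoff_pct or h.evalue > evalue_cutoff:
            continue
        key = (h.query_id, h.subject_id)
        if key not in passing or h.score > passing[key].score:
            passing[key] = h
        bkey = (h.query_id, sp_s)
        if bkey not in best_score or h.score > best_score[bkey]:
            best_score[bkey] = h.score
            best[bkey] = [h.subject_id]
        elif h.score == best_score[bkey] and h.subject_id not in best[bkey]:
            best[bkey].append(h.subject_id)
    g = nx.Graph()
    g.add_nodes_from(sorted(species_of))
    for (qid, sid), hit in sorted(passing.items()):
        if qid >= sid:
            continue
        back = passing.get((sid, qid))
        if back is None:
            continue
        if sid in best.get((qid, species_of[sid]), []) \
                and qid in best.get((sid, species_of[qid]), []):
            g.add_edge(qid, sid, weight=float(hit.score + back.score) / 2.0)
    return g


@dataclass
class MclResult:
    clusters: list[list[str]]  # sorted node lists, sorted by first member
    converged: bool
    n_iter: int


def markov_cluster(graph: nx.Graph, inflation: float = 1.5, expansion: int = 2,
                   max_iter: int = 100, prune_below: float = 1e-5,
                   converge_tol: float = 1e-6) -> MclResult:
    """Deterministic dense MCL on the weighted adjacency with self-loops.

    Self-loop weight per node is its maximum incident edge weight (1 for
    isolated nodes).  Returns the partition plus a convergence flag; a
    non-converged run still returns the current partition.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return MclResult([], True, 0)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    m[np.diag_indices(n)] = loops
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < converge_tol:
            converged = True
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune_below)
    for r, c in zip(rows, cols):
        if r != c:
            support.add_edge(int(r), int(c))
    comps = [sorted(nodes[i] for i in comp)
             for comp in nx.connected_components(support)]
    comps.sort(key=lambda c: c[0])
    return MclResult(comps, converged, it)


def assign_lineage_specificity(members: list[tuple[str, str]],
                               lineage_config: LineageConfig,
                               outgroup_hit_ids: set[str] | None = None) -> str:
    """Label one cluster: "All" when members span every configured lineage;
    a lineage name when all members belong to it, enough distinct species
    carry it, and no member hits the outgroup; "unassigned" otherwise."""
    outgroup_hit_ids = outgroup_hit_ids or set()
    lineages = set()
    species = set()
    for sp, tid in members:
        if sp not in lineage_config.species_to_lineage:
            raise KeyError(f"species {sp!r} missing from lineage configuration")
        lineages.add(lineage_config.species_to_lineage[sp])
        species.add(sp)
    if lineages == set(lineage_config.lineages):
        return "All"
    if len(lineages) == 1 and len(species) >= lineage_config.min_species_transcribed:
        if not any(tid in outgroup_hit_ids for _, tid in members):
            return next(iter(lineages))
    return "unassigned"


def cluster_transcripts(all_hits: list[PairwiseHit], species_of: dict[str, str],
                        cutoffs: list[float], lineage_config: LineageConfig,
                        outgroup_hit_ids: set[str] | None = None,
                        inflation: float = 1.5,
                        evalue_cutoff: float = 1e-10
                        ) -> dict[float, list[HomologyCluster]]:
    """Independent RBH+MCL clustering at each identity cutoff, with lineage
    labels attached.  Every transcript lands in exactly one cluster per cutoff
    (unconnected transcripts become singletons)."""
    out: dict[float, list[HomologyCluster]] = {}
    for cutoff in cutoffs:
        graph = build_rbh_graph(all_hits, species_of, cutoff, evalue_cutoff)
        result = markov_cluster(graph, inflation=inflation)
        clusters = []
        for i, node_ids in enumerate(result.clusters):
            members = sorted((species_of[t], t) for t in node_ids)
            label = assign_lineage_specificity(members, lineage_config,
                                               outgroup_hit_ids)
            clusters.append(HomologyCluster(
                cluster_id=f"C{int(cutoff)}_{i:04d}",
                members=members,
                cutoff_pct=cutoff,
                lineage_label=label,
            ))
        out[cutoff] = clusters
    return out
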