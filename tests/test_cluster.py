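"""RBH graph construction, Markov clustering, lineage specificity."""
import networkx as nx
import numpy as np
import pytest

from synterna.align import PairwiseHit
from synterna.cluster import (LineageConfig, assign_lineage_specificity,
                              build_rbh_graph, cluster_transcripts,
                              markov_cluster)


def hit(q, s, identity=80.0, score=100, ev=1e-30):
    return PairwiseHit(q, s, identity, 100, score, ev)


SPECIES = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}


def reference_mcl(graph, inflation=2.0, expansion=2, iters=60):
    """Straightforward MCL written independently of the package version:
    scipy-free dense matrix powers, loop value 1, hard support threshold."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0)
    for _ in range(iters):
        m = np.linalg.matrix_power(m, expansion) ** inflation
        m /= m.sum(axis=0)
    support = m > 1e-6
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for r, c in zip(*np.nonzero(support)):
        g.add_edge(int(r), int(c))
    return sorted(sorted(nodes[i] for i in comp)
                  for comp in nx.connected_components(g))


class TestRbhGraph:
    def test_mutual_best_passing_cutoffs_gives_edge(self):
        hits = [hit("a1x", "b1x"), hit("b1x", "a1x")]
        g = build_rbh_graph(hits, {"a1x": "A", "b1x": "B"}, 50.0)
        assert g.has_edge("a1x", "b1x")

    def test_reciprocity_required(self):
        species = {"ax": "A", "ay": "A", "bx": "B"}
        hits = [hit("ax", "bx", score=100),  # ax's best in B is bx ...
                hit("bx", "ax", score=50),   # ... but bx's best in A is ay
                hit("bx", "ay", score=80),
                hit("ay", "bx", score=80)]
        g = build_rbh_graph(hits, species, 10.0)
        assert not g.has_edge("ax", "bx")
        assert g.has_edge("ay", "bx")

    def test_identity_cutoff_gates_edges(self):
        hits = [hit("a1x", "b1x", identity=45.0), hit("b1x", "a1x", identity=45.0)]
        species = {"a1x": "A", "b1x": "B"}
        assert not build_rbh_graph(hits, species, 50.0).edges
        assert build_rbh_graph(hits, species, 20.0).has_edge("a1x", "b1x")

    def test_within_species_hits_ignored(self):
        hits = [hit("a1x", "a2x"), hit("a2x", "a1x")]
        g = build_rbh_graph(hits, {"a1x": "A", "a2x": "A"}, 10.0)
        assert not g.edges


class TestMarkovCluster:
    def test_disjoint_triangles_stay_separate(self):
        g = nx.Graph()
        g.add_edges_from([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        res = markov_cluster(g)
        assert res.clusters == [[1, 2, 3], [4, 5, 6]]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_nodes_from(["x"])
        g.add_edges_from([("a", "b")])
        res = markov_cluster(g)
        assert ["x"] in res.clusters

    def test_barbell_splits_at_bridge(self):
        g = nx.Graph()
        left = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        right = [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        g.add_edges_from(left + right + [(3, 4)])
        res = markov_cluster(g, inflation=2.0)
        assert sorted(res.clusters) == reference_mcl(g, inflation=2.0)
        assert sorted(res.clusters) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_deterministic_and_never_spans_components(self, rng):
        """Clusters of random graphs with <= 8 nodes never join disconnected
        components, and re-running is bit-identical."""
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.8)),
                                    seed=int(rng.integers(0, 2**31)))
            res1 = markov_cluster(g)
            res2 = markov_cluster(g)
            assert res1.clusters == res2.clusters
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for node in comp:
                    comp_of[node] = ci
            for cluster in res1.clusters:
                assert len({comp_of[v] for v in cluster}) == 1


class TestLineageSpecificity:
    CFG = LineageConfig({"a1": "A", "a2": "A", "b1": "B", "c1": "C"})

    def test_all_lineages_spanned(self):
        members = [("a1", "t1"), ("b1", "t2"), ("c1", "t3")]
        assert assign_lineage_specificity(members, self.CFG) == "All"

    def test_single_lineage_enough_species(self):
        members = [("a1", "t1"), ("a2", "t2")]
        assert assign_lineage_specificity(members, self.CFG) == "A"

    def test_single_species_unassigned(self):
        assert assign_lineage_specificity([("a1", "t1")], self.CFG) == "unassigned"

    def test_outgroup_hit_blocks_lineage_label(self):
        members = [("a1", "t1"), ("a2", "t2")]
        assert assign_lineage_specificity(members, self.CFG, {"t2"}) == "unassigned"

    def test_unknown_species_is_config_error(self):
        with pytest.raises(KeyError):
            assign_lineage_specificity([("zz", "t1")], self.CFG)


class TestCutoffNesting:
    def test_cluster_count_non_decreasing_in_cutoff(self, rng):
        """On a shared hit set, raising the identity cutoff only removes
        edges, so the partition only gets finer."""
        ids = [f"{sp}x{i}" for sp in SPECIES for i in range(3)]
        species_of = {t: t[:2] for t in ids}
        hits = []
        for i, q in enumerate(ids):
            for s in ids[i + 1:]:
                if SPECIES[species_of[q]] == SPECIES[species_of[s]]:
                    continue
                ident = float(rng.uniform(5, 95))
                score = int(ident * 2)
                hits.append(hit(q, s, identity=ident, score=score))
                hits.append(hit(s, q, identity=ident, score=score))
        cfg = LineageConfig(SPECIES)
        clusters = cluster_transcripts(hits, species_of, [10.0, 20.0, 50.0], cfg)
        counts = [len(clusters[c]) for c in (10.0, 20.0, 50.0)]
        assert counts == sorted(counts)
        for c in (10.0, 20.0, 50.0):
            members = sorted(t for cl in clusters[c] for t in cl.transcript_ids)
            assert members == sorted(ids)  # partition covers every transcript
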