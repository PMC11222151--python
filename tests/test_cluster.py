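"""Threshold graphs, Leiden species clustering, MCL and rank hierarchy."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilvirome import cluster
from soilvirome.cluster import ClusterSet, MclParams


def ani_row(a, b, ani, af_q, af_s):
    return {"query_id": a, "subject_id": b, "ani": ani, "af_query": af_q,
            "af_subject": af_s, "n_alignments": 1}


class TestBuildVotuGraph:
    LENGTHS = {"a": 1_000, "b": 2_000, "c": 1_500, "d": 900, "e": 800}

    def test_inclusive_boundary_pair_connected(self):
        table = pd.DataFrame([ani_row("a", "b", 95.0, 85.0, 42.5)])
        g = cluster.build_votu_graph(table, ["a", "b"], self.LENGTHS)
        assert g.has_edge("a", "b")  # af of shorter ("a") is 85.0, inclusive

    def test_below_threshold_no_edge(self):
        table = pd.DataFrame([ani_row("a", "b", 94.9, 100.0, 50.0)])
        g = cluster.build_votu_graph(table, ["a", "b"], self.LENGTHS)
        assert not g.has_edge("a", "b")

    def test_af_of_longer_sequence_is_ignored(self):
        # shorter genome fully covered, longer one barely: edge exists
        table = pd.DataFrame([ani_row("a", "b", 99.0, 90.0, 45.0)])
        g = cluster.build_votu_graph(table, ["a", "b"], self.LENGTHS)
        assert g.has_edge("a", "b")
        g2 = cluster.build_votu_graph(table, ["a", "b"], self.LENGTHS, af_mode="both")
        assert not g2.has_edge("a", "b")

    def test_isolated_genomes_become_singletons(self):
        g = cluster.build_votu_graph(pd.DataFrame(columns=["query_id", "subject_id",
                                     "ani", "af_query", "af_subject", "n_alignments"]),
                                     list("abcde"), self.LENGTHS)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0


class TestLeidenCluster:
    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        cs = cluster.leiden_cluster(g, seed=1)
        assert sorted(map(len, cs.clusters)) == [1, 1, 1, 1]

    def test_disjoint_cliques_recovered(self):
        g = nx.Graph()
        k4 = ["a", "b", "c", "d"]
        k3 = ["x", "y", "z"]
        g.add_edges_from((u, v) for i, u in enumerate(k4) for v in k4[i + 1:])
        g.add_edges_from((u, v) for i, u in enumerate(k3) for v in k3[i + 1:])
        cs = cluster.leiden_cluster(g, seed=1)
        assert sorted(sorted(c) for c in cs.clusters) == [sorted(k4), sorted(k3)]

    def test_matches_connected_components_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.08, seed=seed)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            cs = cluster.leiden_cluster(g, seed=seed)
            expected = sorted(sorted(c) for c in nx.connected_components(g))
            assert sorted(sorted(c) for c in cs.clusters) == expected


def dense_mcl_reference(g, inflation=2.0, expansion=2, tol=1e-12, max_iter=500,
                        structure_floor=1e-5):
    """Dense, no-pruning MCL iteration run to convergence (test oracle)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    for i, node in enumerate(nodes):
        w = [g.edges[node, nb].get("weight", 1.0) for nb in g.neighbors(node)]
        A[i, i] = max(w) if w else 1.0
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        prev = M
        E = np.linalg.matrix_power(M, expansion)
        E = np.power(E, inflation)
        M = E / E.sum(axis=0)
        if np.abs(M - prev).max() < tol:
            break
    structure = nx.from_numpy_array((M + M.T) > structure_floor)
    comps = [sorted(nodes[i] for i in c) for c in nx.connected_components(structure)]
    return sorted(comps)


class TestMcl:
    def test_disconnected_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        cs = cluster.mcl(g)
        assert sorted(sorted(c) for c in cs.clusters) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_barbell_splits_at_bridge(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")])
        cs = cluster.mcl(g)
        assert sorted(sorted(c) for c in cs.clusters) == [["a", "b", "c"], ["x", "y", "z"]]
        assert sorted(sorted(c) for c in cs.clusters) == dense_mcl_reference(g)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("solo")
        cs = cluster.mcl(g)
        assert cs.clusters == [["solo"]]

    def test_never_merges_components(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=seed)
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.5, 2.0))
            cs = cluster.mcl(g)
            comp_of = {}
            for i, comp in enumerate(nx.connected_components(g)):
                for n in comp:
                    comp_of[n] = i
            for members in cs.clusters:
                assert len({comp_of[m] for m in members}) == 1


class TestClusterRanks:
    def aai_row(self, a, b, aai, shared):
        return {"genome_a": a, "genome_b": b, "aai": aai,
                "shared_gene_fraction": shared, "n_hits": 5}

    def test_threshold_membership(self):
        lengths = {"a": 1_000, "b": 1_000, "c": 1_000}
        table = pd.DataFrame([
            self.aai_row("a", "b", 45.0, 25.0),   # genus + family edge
            self.aai_row("b", "c", 25.0, 15.0),   # family edge only
        ])
        genus, family = cluster.cluster_ranks(table, ["a", "b", "c"], lengths)
        assert genus.labels["a"] == genus.labels["b"] != genus.labels["c"]
        assert len({family.labels[g] for g in "abc"}) == 1

    def test_empty_table_all_singletons(self):
        lengths = {"a": 1, "b": 1}
        table = pd.DataFrame(columns=["genome_a", "genome_b", "aai",
                                      "shared_gene_fraction", "n_hits"])
        genus, family = cluster.cluster_ranks(table, ["a", "b"], lengths)
        assert len(genus) == len(family) == 2

    def test_partition_and_nesting_invariants(self):
        rng = np.random.default_rng(3)
        genomes = [f"g{i}" for i in range(12)]
        lengths = {g: int(rng.integers(1_000, 9_000)) for g in genomes}
        rows = []
        for i, a in enumerate(genomes):
            for b in genomes[i + 1:]:
                aai = float(rng.uniform(10, 60))
                shared = float(rng.uniform(5, 50))
                rows.append(self.aai_row(a, b, aai, shared))
        genus, family = cluster.cluster_ranks(pd.DataFrame(rows), genomes, lengths)
        for cs in (genus, family):
            members = sorted(m for c in cs.clusters for m in c)
            assert members == sorted(genomes)  # partition
        fam_label = family.labels
        for members in genus.clusters:  # nesting after repair
            assert len({fam_label[m] for m in members}) == 1


class TestRepairHierarchy:
    def test_straddling_fine_cluster_moved_to_representatives_home(self):
        lengths = {"a": 9_000, "b": 1_000, "c": 1_000}
        fine = ClusterSet("genus", [["a", "b"], ["c"]])
        coarse = ClusterSet("family", [["a", "c"], ["b"]])
        repaired = cluster.repair_hierarchy(fine, coarse, lengths)
        lab = repaired.labels
        assert lab["a"] == lab["b"]  # b follows representative a


class TestPickRepresentative:
    @pytest.mark.parametrize(
        "members, lengths, expected",
        [
            (["A", "B"], {"A": 5_000, "B": 7_000}, "B"),
            (["A", "B"], {"A": 5_000, "B": 5_000}, "A"),
            (["only"], {"only": 10}, "only"),
        ],
    )
    def test_longest_then_lexicographic(self, members, lengths, expected):
        assert cluster.pick_representative(members, lengths) == expected

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            cluster.pick_representative([], {})
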