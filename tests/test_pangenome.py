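"""Similarity edges, the three clustering modes and the pangenome matrices."""

import numpy as np
import pytest

from pancore import pangenome
from pancore.pangenome import (
    SimilarityEdge,
    cluster_connected,
    cluster_greedy,
    pairwise_similarity,
    read_external_clusters,
    read_pangenome_lst,
    write_pangenome,
)
from tests.conftest import truth_family_of_genes


def edge(a, b):
    return SimilarityEdge(a, b, 1.0, 1.0, 1.0)


class TestPairwiseSimilarity:
    def test_identical_proteins_full_edge(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        (e,) = pairwise_similarity([("a", prot), ("b", prot)])
        assert e.identity == 1.0
        assert e.coverage_a == 1.0 and e.coverage_b == 1.0

    def test_half_length_fragment_fails_coverage(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPD"
        assert pairwise_similarity([("a", prot), ("b", prot[: len(prot) // 2])]) == []

    def test_empty_protein_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            edges = pairwise_similarity([("a", ""), ("b", "MKLV" * 30)])
        assert edges == []

    def test_prefilter_does_not_change_results(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prots = []
        base = "".join(rng.choice(list(aas), size=120))
        prots.append(("p0", base))
        prots.append(("p1", base[:60] + "".join(rng.choice(list(aas), size=60))))
        prots.append(("p2", "".join(rng.choice(list(aas), size=120))))
        with_pf = pairwise_similarity(prots, prefilter=True)
        without = pairwise_similarity(prots, prefilter=False)
        assert with_pf == without

    def test_fixture_edges_only_within_families(
        self, planted_small, annotated_small
    ):
        lookup = truth_family_of_genes(planted_small, annotated_small)
        edges = pairwise_similarity(annotated_small.proteins())
        seen_pairs = set()
        for e in edges:
            assert lookup[e.gene_a] == lookup[e.gene_b]
            assert e.identity >= 0.8
            seen_pairs.add(frozenset((e.gene_a, e.gene_b)))
        # and every within-family pair is connected
        by_family = {}
        for gid, fid in lookup.items():
            by_family.setdefault(fid, []).append(gid)
        for members in by_family.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert frozenset((a, b)) in seen_pairs


class TestClusterConnected:
    def test_transitive_merge(self):
        m = cluster_connected([edge("A", "B"), edge("B", "C")], ["A", "B", "C", "D"])
        assert list(m.families.values()) == [["A", "B", "C"], ["D"]]

    def test_no_edges_all_singletons(self):
        m = cluster_connected([], ["A", "B"])
        assert m.n_families == 2

    def test_complete_graph_single_family(self):
        genes = ["A", "B", "C"]
        edges = [edge(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        assert cluster_connected(edges, genes).n_families == 1

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            cluster_connected([edge("A", "Z")], ["A", "B"])

    def test_matches_transitive_closure_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 60
            genes = [f"g{i:03d}" for i in range(n)]
            adj = rng.random((n, n)) < 0.03
            adj = np.triu(adj, 1)
            edges = [
                edge(genes[i], genes[j]) for i, j in zip(*np.nonzero(adj))
            ]
            m = cluster_connected(edges, genes)
            # oracle: boolean transitive closure by repeated squaring
            reach = adj | adj.T | np.eye(n, dtype=bool)
            for _ in range(int(np.ceil(np.log2(n))) + 1):
                reach = reach @ reach
            oracle = {
                frozenset(np.nonzero(row)[0].tolist()) for row in reach
            }
            mine = {
                frozenset(genes.index(g) for g in mem)
                for mem in m.families.values()
            }
            assert mine == oracle

    def test_family_ids_ordered_by_smallest_member(self):
        m = cluster_connected([edge("B", "C")], ["B", "C", "A"])
        assert m.families[1] == ["A"] and m.families[2] == ["B", "C"]


class TestClusterGreedy:
    def test_set_cover_path_graph(self):
        m = cluster_greedy([edge("A", "B"), edge("B", "C")], ["A", "B", "C"],
                           mode="set_cover")
        assert list(m.families.values()) == [["A", "B", "C"]]

    def test_greedy_incremental_path_graph(self):
        m = cluster_greedy([edge("A", "B"), edge("B", "C")], ["A", "B", "C"],
                           mode="greedy_incremental")
        assert list(m.families.values()) == [["A", "B"], ["C"]]

    def test_no_edges_matches_connected(self):
        genes = ["A", "B", "C"]
        for mode in ("set_cover", "greedy_incremental"):
            m = cluster_greedy([], genes, mode=mode)
            assert m.families == cluster_connected([], genes).families

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cluster_greedy([], ["A"], mode="nope")

    def test_partition_and_nesting_in_connected(self):
        rng = np.random.default_rng(23)
        n = 40
        genes = [f"g{i:02d}" for i in range(n)]
        edges = [
            edge(genes[i], genes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.05
        ]
        coarse = cluster_connected(edges, genes)
        for mode in ("set_cover", "greedy_incremental"):
            fine = cluster_greedy(edges, genes, mode=mode)
            assert sum(len(m) for m in fine.families.values()) == n
            # every fine family sits inside exactly one connected component
            comp_of = {
                g: fid for fid, mem in coarse.families.items() for g in mem
            }
            for mem in fine.families.values():
                assert len({comp_of[g] for g in mem}) == 1


class TestMatrixAndIO:
    def test_copy_number_vs_presence(self, planted_small, annotated_small):
        lookup = truth_family_of_genes(planted_small, annotated_small)
        edges = pairwise_similarity(annotated_small.proteins())
        m = cluster_connected(edges, [g for g, _ in annotated_small.proteins()])
        assert m.n_families == planted_small.n_families
        # some planted multi-copy cell must show counts 2, presence 1
        assert (m.counts.values >= 2).any()
        assert set(np.unique(m.presence.values)) <= {0, 1}
        # column sums = per-genome gene totals
        totals = {
            name: len(recs) for name, recs in annotated_small.records.items()
        }
        for genome, total in totals.items():
            assert m.counts[genome].sum() == total

    def test_write_read_round_trip(self, tmp_path):
        m = cluster_connected([edge("A", "B")], ["A", "B", "C"])
        paths = write_pangenome(m, tmp_path)
        back = read_pangenome_lst(paths["lst"])
        assert back.families == m.families
        assert back.counts.equals(m.counts)

    def test_external_clusters_single_family(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("A\tA\nA\tB\nA\tC\n")
        m = read_external_clusters(p, ["A", "B", "C"])
        assert m.n_families == 1

    def test_external_clusters_duplicate_membership_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("A\tA\nA\tB\nC\tB\nC\tC\n")
        with pytest.raises(ValueError, match="partition"):
            read_external_clusters(p, ["A", "B", "C"])

    def test_presence_matrix_single_genome(self, tmp_path):
        genes = ["TEST.0121.00001.0001b_00001", "TEST.0121.00001.0001i_00002"]
        m = cluster_connected([], genes)
        assert m.genomes == ["TEST.0121.00001"]
        paths = write_pangenome(m, tmp_path)
        lines = paths["presence"].read_text().splitlines()
        assert [l.split("\t")[1] for l in lines[1:]] == ["1", "1"]


def test_subset_clustering_nests_in_full_clustering(planted_small, annotated_small):
    """Families from a genome subset are each contained in one full-set family."""
    all_prot = annotated_small.proteins()
    full = cluster_connected(
        pairwise_similarity(all_prot), [g for g, _ in all_prot]
    )
    subset_names = sorted(annotated_small.records)[:2]
    sub_prot = [
        (rec.gene_id, rec.protein_seq)
        for name in subset_names
        for rec in annotated_small.records[name]
    ]
    sub = cluster_connected(
        pairwise_similarity(sub_prot), [g for g, _ in sub_prot]
    )
    family_of = {g: fid for fid, mem in full.families.items() for g in mem}
    for mem in sub.families.values():
        assert len({family_of[g] for g in mem}) == 1
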