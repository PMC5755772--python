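import networkx as nx
import numpy as np
import pytest

from osteomap.autocm import DistanceMatrix
from osteomap.cohort import CohortTable
from osteomap.graphs import (
    MRG,
    MST,
    SemanticGraph,
    compare_maps,
    find_hubs,
    maximally_regular_graph,
    minimum_spanning_tree,
    read_graphml,
    regularity_score,
    subgroup_maps,
    write_dot,
    write_edgelist_csv,
    write_graphml,
)

from _oracles import brute_force_mst_total
from _util import distance_matrix_from_dict


def _graph(edges, kind=MST):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, distance=1.0)
    return SemanticGraph(graph=g, kind=kind)


class TestMst:
    def test_chain_example_beats_all_16_trees_of_k4(self):
        d = distance_matrix_from_dict(
            ["A", "B", "C", "D"],
            {("A", "B"): 0.1, ("B", "C"): 0.2, ("C", "D"): 0.3},
            default=0.9,
        )
        mst = minimum_spanning_tree(d)
        assert mst.edge_set == {("A", "B"), ("B", "C"), ("C", "D")}
        total = sum(data["distance"] for *_, data in mst.graph.edges(data=True))
        assert total == pytest.approx(0.6)
        assert total == pytest.approx(brute_force_mst_total(d.d))

    def test_two_nodes_single_edge(self):
        d = distance_matrix_from_dict(["A", "B"], {}, default=0.5)
        mst = minimum_spanning_tree(d)
        assert mst.edge_set == {("A", "B")}

    def test_equal_distances_give_star_at_first_label(self):
        d = distance_matrix_from_dict(["A", "B", "C", "D"], {}, default=0.5)
        mst = minimum_spanning_tree(d)
        assert mst.edge_set == {("A", "B"), ("A", "C"), ("A", "D")}
        # any spanning tree has the same total under equal distances
        assert brute_force_mst_total(d.d) == pytest.approx(1.5)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 8))
            a = rng.random((n, n))
            dmat = (a + a.T) / 2
            np.fill_diagonal(dmat, 0.0)
            dmat /= dmat.max()
            d = DistanceMatrix(labels=[f"n{i:02d}" for i in range(n)], d=dmat)
            mst = minimum_spanning_tree(d)
            total = sum(w["distance"] for *_, w in mst.graph.edges(data=True))
            assert total == pytest.approx(brute_force_mst_total(dmat))

    def test_matches_networkx_total(self):
        rng = np.random.default_rng(23)
        a = rng.random((10, 10))
        dmat = (a + a.T) / 2
        np.fill_diagonal(dmat, 0.0)
        dmat /= dmat.max()
        d = DistanceMatrix(labels=[f"n{i:02d}" for i in range(10)], d=dmat)
        mst = minimum_spanning_tree(d)
        g = nx.from_numpy_array(dmat)
        ref = nx.minimum_spanning_tree(g, weight="weight")
        ours = sum(w["distance"] for *_, w in mst.graph.edges(data=True))
        theirs = ref.size(weight="weight")
        assert ours == pytest.approx(theirs)

    def test_tree_shape_invariants(self):
        d = distance_matrix_from_dict(["A", "B", "C", "D", "E"], {}, default=0.3)
        mst = minimum_spanning_tree(d)
        assert mst.n_edges == 4
        assert nx.is_tree(mst.graph)


class TestRegularityScore:
    def test_tree_scores_zero(self):
        assert regularity_score(_graph([("a", "b"), ("b", "c")]), 0) == 0.0

    def test_triangle_scores_half(self):
        g = _graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert regularity_score(g, 1) == pytest.approx(0.5)

    def test_square_with_diagonal_has_no_regular_cycles(self):
        g = _graph(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
        )
        # both basis triangles contain the degree-3 diagonal endpoints
        assert regularity_score(g, 2) == 0.0

    def test_disconnected_rejected(self):
        g = _graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            regularity_score(g, 0)


class TestMrg:
    def test_all_equal_three_nodes_gives_triangle(self):
        d = distance_matrix_from_dict(["A", "B", "C"], {}, default=0.4)
        mrg = maximally_regular_graph(d)
        assert mrg.edge_set == {("A", "B"), ("A", "C"), ("B", "C")}
        assert mrg.kind == MRG

    def test_short_chord_closing_regular_cycle_is_added(self):
        # path MST A-..-F plus one cheap chord closing the 6-cycle: every
        # node then has degree 2, one regular basis cycle, H = 1/2
        labels = ["A", "B", "C", "D", "E", "F"]
        entries = {("A", "B"): 0.1, ("B", "C"): 0.1, ("C", "D"): 0.1,
                   ("D", "E"): 0.1, ("E", "F"): 0.1, ("A", "F"): 0.2}
        d = distance_matrix_from_dict(labels, entries, default=0.9)
        mst = minimum_spanning_tree(d)
        assert mst.edge_set == {("A", "B"), ("B", "C"), ("C", "D"),
                                ("D", "E"), ("E", "F")}
        mrg = maximally_regular_graph(d, mst)
        assert mrg.edge_set == mst.edge_set | {("A", "F")}

    def test_unhelpful_chord_leaves_mst(self):
        d = distance_matrix_from_dict(
            ["A", "B", "C", "D"],
            {("A", "B"): 0.1, ("A", "C"): 0.2, ("A", "D"): 0.3},
            default=0.95,
        )
        mst = minimum_spanning_tree(d)
        # star MST: one chord creates a triangle mixing the degree-3 hub A
        # with degree-2 leaves, so no equal-degree cycle appears and H stays 0
        mrg = maximally_regular_graph(d, mst, k_max=1)
        assert mrg.edge_set == mst.edge_set

    def test_mrg_superset_of_mst(self, pipeline_run):
        cfg, _ = pipeline_run
        from pathlib import Path

        mst = read_graphml(Path(cfg.outdir) / "mst.graphml", MST)
        mrg = read_graphml(Path(cfg.outdir) / "mrg.graphml", MRG)
        assert mrg.edge_set >= mst.edge_set


class TestHubs:
    def test_star_center_first(self):
        g = _graph([("c", x) for x in "abde"])
        ranked = find_hubs(g)
        assert ranked[0] == "c"
        assert g.graph.nodes["c"]["degree"] == 4
        assert g.graph.nodes["c"]["hub_rank"] == 1

    def test_path_interior_before_leaves(self):
        g = _graph([("a", "b"), ("b", "c"), ("c", "d")])
        ranked = find_hubs(g)
        assert set(ranked[:2]) == {"b", "c"}
        assert set(ranked[2:]) == {"a", "d"}

    def test_ties_lexicographic(self):
        g = _graph([("a", "b"), ("c", "d")])
        g.graph.add_node("e")
        assert find_hubs(g) == ["a", "b", "c", "d", "e"]


class TestSubgroupsAndComparison:
    def test_subgroup_maps_drop_fracture_node(self, cohort_125):
        maps = subgroup_maps(cohort_125)
        for g in maps.values():
            assert not any("Fracture" in n for n in g.nodes)
            assert g.kind == MRG

    def test_subgroup_too_small_rejected(self, cohort_125):
        df = cohort_125.data.copy()
        df["SDI"] = 0.0
        df.loc[df.index[0], "SDI"] = 6.0
        with pytest.raises(ValueError, match="VFx_yes"):
            subgroup_maps(CohortTable(cohort_125.schema, df))

    def test_constant_subgroup_column_listed(self, cohort_125):
        df = cohort_125.data.copy()
        mask = df["SDI"] > 5
        df.loc[mask, "TBS"] = 1.0
        with pytest.raises(ValueError, match="TBS"):
            subgroup_maps(CohortTable(cohort_125.schema, df))

    def test_identical_graphs_jaccard_one(self):
        g = _graph([("a", "b"), ("b", "c")])
        assert compare_maps(g, g)["jaccard"] == 1.0

    def test_disjoint_graphs_jaccard_zero(self):
        a = _graph([("a", "b")])
        b = _graph([("c", "d")])
        assert compare_maps(a, b)["jaccard"] == 0.0

    def test_mst_vs_its_mrg_superset_arithmetic(self):
        d = distance_matrix_from_dict(["A", "B", "C"], {}, default=0.4)
        mst = minimum_spanning_tree(d)
        mrg = maximally_regular_graph(d, mst)
        k = mrg.n_edges - mst.n_edges
        n = len(mst.nodes)
        rep = compare_maps(mst, mrg)
        assert rep["jaccard"] == pytest.approx((n - 1) / (n - 1 + k))

    def test_empty_union_rejected(self):
        a = SemanticGraph(graph=nx.Graph(), kind=MST)
        with pytest.raises(ValueError):
            compare_maps(a, a)


class TestWriters:
    def test_graphml_round_trip_preserves_edges(self, tmp_path):
        g = _graph([("a", "b"), ("b", "c")])
        find_hubs(g)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        back = read_graphml(path)
        assert back.edge_set == g.edge_set

    def test_dot_and_csv_outputs(self, tmp_path):
        g = _graph([("a", "b")])
        find_hubs(g)
        write_dot(g, tmp_path / "g.dot")
        write_edgelist_csv(g, tmp_path / "g.csv")
        dot = (tmp_path / "g.dot").read_text()
        assert '"a" -- "b"' in dot
        csv = (tmp_path / "g.csv").read_text()
        assert csv.splitlines()[0] == "node1,node2,distance"
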