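"""MST filtering, hubness, maximally regular graph, map deltas, export."""

import networkx as nx
import numpy as np
import pytest

from osteomap import graphs
from osteomap.graphs import (
    compare_counts,
    compare_maps,
    export_graph,
    find_hubs,
    hubness,
    maximally_regular_graph,
    minimum_spanning_tree,
    read_edge_list,
)

from _oracles import (
    all_spanning_tree_edges,
    min_spanning_total,
    mrg_prefix_max_hubness,
    nx_hubness,
)


def _random_distance(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMST:
    def test_three_node_unique_tree(self):
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        g = minimum_spanning_tree(d)
        assert set(map(frozenset, g.edges)) == {frozenset({0, 1}), frozenset({0, 2})}

    def test_matches_exhaustive_minimum_100_matrices(self):
        trees = all_spanning_tree_edges(7)
        for seed in range(100):
            d = _random_distance(7, seed)
            g = minimum_spanning_tree(d)
            assert g.number_of_edges() == 6
            assert nx.is_connected(g)
            total = sum(a["distance"] for *_, a in g.edges(data=True))
            assert total == pytest.approx(min_spanning_total(d, trees), abs=1e-12)

    def test_equal_distances_deterministic_tiebreak(self):
        d = np.ones((5, 5)) - np.eye(5)
        g1 = minimum_spanning_tree(d)
        g2 = minimum_spanning_tree(d)
        assert sorted(g1.edges) == sorted(g2.edges)
        # lexicographic Kruskal on a uniform matrix yields the star at node 0
        assert sorted(g1.edges) == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            minimum_spanning_tree(d)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="finite"):
            minimum_spanning_tree(d)


class TestHubness:
    def test_trees_have_zero_hubness(self):
        assert hubness(nx.path_graph(6)) == 0.0
        assert hubness(nx.star_graph(5)) == 0.0

    def test_triangle(self):
        # one 3-cycle over 1 + (3 edges - 2 tree edges) = 2
        assert hubness(nx.complete_graph(3)) == 0.5

    def test_k4_exhaustive(self):
        # 4 triangles + 3 quadrilaterals over 1 + (6 - 3) extra edges
        assert hubness(nx.complete_graph(4)) == pytest.approx(7 / 4)

    def test_matches_generic_cycle_enumerator(self):
        checked = 0
        for seed in range(30):
            g = nx.gnp_random_graph(7, 0.45, seed=seed)
            if not nx.is_connected(g):
                continue
            assert hubness(g) == pytest.approx(nx_hubness(g), abs=1e-12)
            checked += 1
        assert checked >= 15

    def test_disconnected_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            hubness(g)


class TestMRG:
    def test_attains_prefix_maximum_50_instances(self):
        for seed in range(50):
            d = _random_distance(6, 1000 + seed)
            mst = minimum_spanning_tree(d)
            mrg = maximally_regular_graph(mst, d)
            assert hubness(mrg) == pytest.approx(
                mrg_prefix_max_hubness(d, mst, 6), abs=1e-12
            )
            assert set(mst.edges) <= set(map(tuple, mrg.edges)) or all(
                mrg.has_edge(a, b) for a, b in mst.edges
            )

    def test_max_extra_zero_returns_mst(self):
        d = _random_distance(6, 3)
        mst = minimum_spanning_tree(d)
        mrg = maximally_regular_graph(mst, d, max_extra=0)
        assert sorted(mrg.edges) == sorted(mst.edges)

    def test_added_edges_flagged(self):
        d = _random_distance(8, 9)
        mst = minimum_spanning_tree(d)
        mrg = maximally_regular_graph(mst, d)
        for a, b, attrs in mrg.edges(data=True):
            expected = "mst" if mst.has_edge(a, b) else "mrg_added"
            assert attrs["flag"] == expected

    def test_disconnected_input_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edge(0, 1)
        with pytest.raises(ValueError, match="connected"):
            maximally_regular_graph(g, _random_distance(4, 0))


class TestHubs:
    def test_path_has_no_hubs(self):
        assert find_hubs(nx.path_graph(5)) == set()

    def test_star_center_is_hub(self):
        assert find_hubs(nx.star_graph(5)) == {0}

    def test_double_star(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b")])
        for i in range(3):
            g.add_edge("a", f"al{i}")
            g.add_edge("b", f"bl{i}")
        assert find_hubs(g) == {"a", "b"}

    def test_monotone_under_edge_addition(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(8, 0.3, seed=seed)
            hubs = find_hubs(g)
            g2 = g.copy()
            non_edges = list(nx.non_edges(g2))
            if not non_edges:
                continue
            g2.add_edge(*non_edges[0])
            assert hubs <= find_hubs(g2)


class TestCompareMaps:
    @pytest.mark.parametrize(
        "e1,h1,e2,h2,edge_pct,hub_pct",
        [
            (22, 9, 33, 10, 50, 11),   # responders before -> after
            (2, 3, 10, 7, 400, 133),   # non-responders before -> after
            (22, 9, 2, 3, -91, -67),   # responders vs non-responders, before
            (33, 10, 10, 7, -70, -30),  # responders vs non-responders, after
        ],
    )
    def test_published_count_deltas(self, e1, h1, e2, h2, edge_pct, hub_pct):
        delta = compare_counts(e1, h1, e2, h2)
        assert delta.edge_change_pct == edge_pct
        assert delta.hub_change_pct == hub_pct

    def test_identical_graphs_zero_delta(self):
        g = nx.complete_graph(5)
        delta = compare_maps(g, g)
        assert delta.edge_change_pct == 0 and delta.hub_change_pct == 0

    def test_zero_baseline_undefined_not_crash(self):
        delta = compare_counts(0, 0, 5, 2)
        assert delta.edge_change_pct is None
        assert delta.hub_change_pct is None


class TestExport:
    def test_edge_list_round_trip(self, tmp_path):
        d = _random_distance(25, 4)
        g = minimum_spanning_tree(d)
        path = tmp_path / "edges.csv"
        export_graph(g, path, format="csv")
        back = read_edge_list(path)
        assert back.number_of_edges() == 24
        for a, b, attrs in back.edges(data=True):
            orig = g.edges[int(a), int(b)]
            assert attrs["strength"] == pytest.approx(orig["strength"], rel=1e-5)
            assert attrs["flag"] == orig["flag"]

    def test_graphml_reparse(self, tmp_path):
        g = minimum_spanning_tree(_random_distance(6, 5))
        path = tmp_path / "g.graphml"
        export_graph(g, path, format="graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 6
        assert back.number_of_edges() == 5

    def test_empty_graph_valid_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_graph(nx.Graph(), path, format="csv")
        assert read_edge_list(path).number_of_edges() == 0

    def test_dot_output(self, tmp_path):
        g = minimum_spanning_tree(_random_distance(4, 6))
        path = tmp_path / "g.dot"
        export_graph(g, path, format="dot")
        text = path.read_text()
        assert text.startswith("graph") and text.count("--") == 3
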