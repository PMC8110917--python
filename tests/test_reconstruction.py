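import networkx as nx
import numpy as np
import pytest

import vesselkit as vk
from vesselkit.errors import ValidationError

from conftest import brute_force_mst_weight, random_connected_graph, random_forest_graph


class TestBuildNeighborGraph:
    def _boxes(self, centers, size=32.0, label="vessel", conf=1.0):
        return vk.DetectionSet(
            "g", [vk.DetectionBox(x, y, size, size, conf, label) for x, y in centers]
        )

    def test_close_boxes_connected_distant_not(self):
        d = np.hypot(32, 32)
        near = self._boxes([(0, 0), (0.5 * d * 1.25, 0)])
        far = self._boxes([(0, 0), (2 * d * 1.25, 0)])
        assert vk.build_neighbor_graph(near, 1.25).number_of_edges() == 1
        assert vk.build_neighbor_graph(far, 1.25).number_of_edges() == 0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(0, 400, (50, 2))
        sizes = rng.uniform(16, 48, 50)
        det = vk.DetectionSet(
            "g",
            [vk.DetectionBox(x, y, s, s, 1.0, "vessel") for (x, y), s in zip(centers, sizes)],
        )
        G = vk.build_neighbor_graph(det, radius_factor=1.25)
        diag = np.hypot(sizes, sizes)
        expected = set()
        for i in range(50):
            for j in range(i + 1, 50):
                dist = np.hypot(*(centers[i] - centers[j]))
                if 0 < dist <= 1.25 * (diag[i] + diag[j]) / 2:
                    expected.add((i, j))
        assert {tuple(sorted(e)) for e in G.edges()} == expected
        for u, v, w in G.edges(data="weight"):
            assert w == pytest.approx(np.hypot(*(centers[u] - centers[v])))

    def test_non_vessel_and_low_confidence_boxes_excluded(self):
        det = vk.DetectionSet(
            "g",
            [
                vk.DetectionBox(0, 0, 32, 32, 1.0, "vessel"),
                vk.DetectionBox(10, 0, 32, 32, 1.0, "debris"),
                vk.DetectionBox(20, 0, 32, 32, 0.2, "vessel"),
            ],
        )
        G = vk.build_neighbor_graph(det, min_confidence=0.5)
        assert G.number_of_nodes() == 1

    def test_empty_detection_set_gives_empty_graph(self):
        G = vk.build_neighbor_graph(vk.DetectionSet("g", []))
        assert G.number_of_nodes() == 0


class TestFilterFalseConnections:
    def test_two_bar_gap_edges_removed_intra_kept(self, two_bar_scene):
        image, det = two_bar_scene
        G = vk.build_neighbor_graph(det)
        inter = {
            tuple(sorted((u, v)))
            for u, v in G.edges()
            if abs(G.nodes[u]["pos"][1] - G.nodes[v]["pos"][1]) > 20
        }
        assert inter, "construction must produce candidate gap edges"
        H = vk.filter_false_connections(G, image)
        kept = {tuple(sorted(e)) for e in H.edges()}
        assert not (kept & inter)
        assert kept == {tuple(sorted(e)) for e in G.edges()} - inter
        assert set(H.nodes()) == set(G.nodes())

    def test_blank_image_removes_all_edges(self, two_bar_scene):
        _, det = two_bar_scene
        G = vk.build_neighbor_graph(det)
        blank = vk.Image2D(np.zeros((120, 200)) + 3.0, 1.0)
        H = vk.filter_false_connections(G, blank)
        assert H.number_of_edges() == 0
        assert H.number_of_nodes() == G.number_of_nodes()

    def test_edge_inside_bright_bar_has_full_support(self, two_bar_scene):
        image, det = two_bar_scene
        G = vk.build_neighbor_graph(det)
        u, v = next(
            (u, v) for u, v in G.edges()
            if abs(G.nodes[u]["pos"][1] - G.nodes[v]["pos"][1]) < 1
        )
        assert vk.edge_support(G, image, u, v) == pytest.approx(1.0)


class TestRemoveCycles:
    def test_triangle_drops_heaviest_edge(self):
        G = nx.Graph()
        G.add_node(0, pos=(0, 0)); G.add_node(1, pos=(3, 0)); G.add_node(2, pos=(0, 4))
        G.add_edge(0, 1, weight=3.0)
        G.add_edge(0, 2, weight=4.0)
        G.add_edge(1, 2, weight=5.0)
        T = vk.remove_cycles(G)
        assert {tuple(sorted(e)) for e in T.edges()} == {(0, 1), (0, 2)}

    def test_forest_is_fixed_point(self):
        rng = np.random.default_rng(8)
        F = random_forest_graph(rng)
        T = vk.remove_cycles(F)
        assert {tuple(sorted(e)) for e in T.edges()} == {tuple(sorted(e)) for e in F.edges()}

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            G = random_connected_graph(rng)
            T = vk.remove_cycles(G)
            w = sum(d for *_, d in T.edges(data="weight"))
            assert w == pytest.approx(brute_force_mst_weight(G), rel=1e-9)
            assert nx.is_forest(T)

    def test_component_partition_preserved(self):
        rng = np.random.default_rng(21)
        G = nx.union(random_connected_graph(rng), random_connected_graph(rng), rename=("a", "b"))
        T = vk.remove_cycles(G)
        assert [set(c) for c in nx.connected_components(T)] == [
            set(c) for c in nx.connected_components(G)
        ]
        assert T.number_of_edges() == T.number_of_nodes() - nx.number_connected_components(T)


class TestGraphToPolylines:
    def test_simple_path_of_collinear_nodes(self):
        F = nx.Graph()
        for i in range(4):
            F.add_node(i, pos=(10.0 * i, 0.0))
        for i in range(3):
            F.add_edge(i, i + 1, weight=10.0)
        polys = vk.graph_to_polylines(F)
        assert len(polys) == 1
        assert vk.polyline_length(polys[0]) == pytest.approx(30.0)

    def test_y_tree_splits_at_branch_node(self):
        F = nx.Graph()
        F.add_node(0, pos=(0.0, 0.0))
        for i, (x, y) in enumerate([(10.0, 0.0), (-10.0, 0.0), (0.0, 10.0)], start=1):
            F.add_node(i, pos=(x, y))
            F.add_edge(0, i, weight=10.0)
        polys = vk.graph_to_polylines(F)
        assert len(polys) == 3
        assert sum(vk.polyline_length(p) for p in polys) == pytest.approx(30.0)

    def test_length_conservation_on_random_forests(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            F = random_forest_graph(rng, n_trees=4)
            polys = vk.graph_to_polylines(F)
            total_edges = sum(d for *_, d in F.edges(data="weight"))
            total_polys = sum(vk.polyline_length(p) for p in polys)
            assert total_polys == pytest.approx(total_edges, rel=1e-9)
            # every edge in exactly one polyline
            n_segments = sum(len(p.points) - 1 for p in polys)
            assert n_segments == F.number_of_edges()

    def test_cyclic_input_rejected(self):
        G = nx.cycle_graph(4)
        for i in G.nodes():
            G.nodes[i]["pos"] = (float(i), 0.0)
        for u, v in G.edges():
            G.edges[u, v]["weight"] = 1.0
        with pytest.raises(ValidationError, match="remove_cycles"):
            vk.graph_to_polylines(G)

    def test_isolated_nodes_yield_no_polyline(self):
        F = nx.Graph()
        F.add_node(0, pos=(0.0, 0.0))
        assert vk.graph_to_polylines(F) == []


class TestReconstruct:
    def test_empty_detections_give_empty_output(self, single_vessel_scene):
        sc = single_vessel_scene
        out = vk.reconstruct(vk.DetectionSet(sc.image.id, []), sc.image)
        assert out == []

    def test_single_vessel_recovered_within_one_stride(self, single_vessel_scene):
        sc = single_vessel_scene
        det = vk.oracle_detect(sc.truth, 32, 16, jitter_sd=0, miss_rate=0, seed=0)
        polys = vk.reconstruct(det, sc.image)
        assert len(polys) == 1
        recovered = sum(vk.polyline_length(p) for p in polys)
        assert abs(recovered - sc.truth_vessel_length_px) <= 16

    def test_deterministic(self, single_vessel_scene):
        sc = single_vessel_scene
        det = vk.oracle_detect(sc.truth, 32, 16, jitter_sd=1.0, miss_rate=0.05, seed=3)
        a = vk.reconstruct(det, sc.image)
        b = vk.reconstruct(det, sc.image)
        assert [p.points for p in a] == [p.points for p in b]

    def test_image_id_mismatch_rejected(self, single_vessel_scene):
        sc = single_vessel_scene
        det = vk.DetectionSet("other-image", [vk.DetectionBox(5, 5, 32, 32)])
        with pytest.raises(ValidationError, match="other-image"):
            vk.reconstruct(det, sc.image)

    def test_pipeline_monotonicity(self, two_bar_scene):
        image, det = two_bar_scene
        G = vk.build_neighbor_graph(det)
        H = vk.filter_false_connections(G, image)
        F = vk.remove_cycles(H)
        assert H.number_of_edges() <= G.number_of_edges()
        assert F.number_of_edges() <= H.number_of_edges()
        assert set(F.nodes()) == set(G.nodes())

    def test_kink_robustness_under_jitter(self):
        # jittered detections on a rendered straight 300 px vessel: kinks
        # offset one another, so median recovered length stays within 10%
        params = vk.SceneParams(field_px=(400, 300), seed=0)
        truth = vk.AnnotationSet(
            params.image_id, [vk.Polyline(((50.0, 150.0), (350.0, 150.0)))]
        )
        image = vk.render(truth, params)
        errors = []
        for seed in range(100):
            det = vk.oracle_detect(truth, 32, 16, jitter_sd=2.0, miss_rate=0.0, seed=seed)
            rec = sum(vk.polyline_length(p) for p in vk.reconstruct(det, image))
            errors.append(abs(rec - 300.0) / 300.0)
        assert np.median(errors) < 0.10
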