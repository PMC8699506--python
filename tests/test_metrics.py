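import networkx as nx
import numpy as np
import pytest

from phonospread import (
    component_partition,
    fragmentation,
    key_players,
    local_clustering,
    node_metrics_table,
    write_node_metrics,
)
from phonospread.errors import ResolutionError, ValidationError

from _oracles import (
    best_single_removal,
    clustering_by_triples,
    components_by_union_find,
    fragmentation_by_definition,
)
from conftest import random_graph


class TestLocalClustering:
    def test_triangle_vertex_is_one(self):
        G = nx.complete_graph(3)
        assert local_clustering(G, 0) == 1.0

    def test_star_center_is_zero(self):
        G = nx.star_graph(4)
        assert local_clustering(G, 0) == 0.0

    def test_one_of_three_neighbor_pairs(self):
        G = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        assert local_clustering(G, "a") == pytest.approx(1 / 3)

    def test_degree_below_two_is_zero_by_convention(self):
        G = nx.path_graph(3)
        assert local_clustering(G, 0) == 0.0  # degree 1
        G.add_node(99)
        assert local_clustering(G, 99) == 0.0  # degree 0

    def test_unknown_node_raises(self):
        with pytest.raises(ResolutionError):
            local_clustering(nx.path_graph(2), 99)

    def test_matches_triple_counting_on_atlas_graphs(self):
        """Exhaustive check on every graph with up to 7 nodes."""
        from networkx.generators.atlas import graph_atlas_g

        for G in graph_atlas_g()[1:]:
            for node in G.nodes():
                assert local_clustering(G, node) == pytest.approx(
                    clustering_by_triples(G, node)
                )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_networkx_on_random_graphs(self, seed):
        G = random_graph(np.random.default_rng(seed), n_max=40)
        ref = nx.clustering(G)
        for node in G.nodes():
            assert local_clustering(G, node) == pytest.approx(ref[node])


class TestComponentPartition:
    def test_triangle_edge_isolate(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
        G.add_node(5)
        part = component_partition(G)
        assert part.giant == frozenset({0, 1, 2})
        assert part.islands == (frozenset({3, 4}),)
        assert part.isolates == frozenset({5})
        assert part.classify(0) == "giant"
        assert part.classify(3) == "island"
        assert part.classify(5) == "isolate"

    def test_edgeless_graph_has_no_giant(self):
        G = nx.empty_graph(4)
        part = component_partition(G)
        assert part.giant == frozenset()
        assert part.isolates == frozenset(range(4))

    def test_empty_graph(self):
        part = component_partition(nx.Graph())
        assert part.components == () and part.giant == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed):
        G = random_graph(np.random.default_rng(seed), n_max=60)
        part = component_partition(G)
        assert set(part.components) == components_by_union_find(G)
        # partition covers node set exactly
        assert sum(len(c) for c in part.components) == G.number_of_nodes()
        # every isolate has degree 0
        assert all(G.degree(v) == 0 for v in part.isolates)
        # giant at least as large as any island
        for island in part.islands:
            assert len(part.giant) >= len(island)


class TestFragmentation:
    def test_connected_graph_is_zero(self):
        assert fragmentation(nx.path_graph(6)) == 0.0

    def test_edgeless_graph_is_one(self):
        assert fragmentation(nx.empty_graph(5)) == 1.0

    def test_two_triads_on_six_nodes(self):
        G = nx.Graph([(0, 1), (1, 2), (3, 4), (4, 5)])
        assert fragmentation(G) == pytest.approx(0.6)  # 1 - 12/30

    def test_undefined_below_two_nodes(self):
        with pytest.raises(ValidationError):
            fragmentation(nx.empty_graph(1))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pairwise_reachability_oracle(self, seed):
        G = random_graph(np.random.default_rng(seed), n_max=30)
        assert fragmentation(G) == pytest.approx(
            fragmentation_by_definition(G)
        )

    def test_monotone_under_edge_deletion(self):
        rng = np.random.default_rng(5)
        G = random_graph(rng, n_max=30)
        f = fragmentation(G)
        for u, v in list(G.edges()):
            H = G.copy()
            H.remove_edge(u, v)
            assert fragmentation(H) >= f - 1e-12


class TestKeyPlayers:
    def test_bridge_between_triangles(self):
        # triangles 0-1-2 and 3-4-5 joined through bridge vertex 6
        G = nx.Graph(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (5, 3), (6, 0), (6, 3)]
        )
        res = key_players(G, 1)
        assert res.selected == frozenset({6})
        assert res.F == pytest.approx(0.6)  # 1 - 12/30

    def test_complete_graph_tie_breaks_to_lowest_id(self):
        res = key_players(nx.complete_graph(4), 1)
        assert res.selected == frozenset({0})
        assert res.F == 0.0

    def test_path_middle_node(self):
        res = key_players(nx.path_graph(5), 1)
        assert res.selected == frozenset({2})
        assert res.F == pytest.approx(2 / 3)

    def test_k_target_out_of_range(self):
        with pytest.raises(ValidationError):
            key_players(nx.path_graph(3), 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_k1_matches_exhaustive_removal(self, seed):
        G = random_graph(np.random.default_rng(seed), n_max=50)
        res = key_players(G, 1)
        _, best_f = best_single_removal(G)
        assert res.F == pytest.approx(best_f)

    def test_k2_on_double_bridge_path(self):
        # path of clusters A - b1 - B - b2 - C: both bridges selected
        G = nx.Graph(
            [
                (0, 1),
                (1, 2),
                (0, 2),  # A
                (3, 0),  # b1 = 3
                (3, 4),
                (4, 5),
                (5, 6),
                (6, 4),  # B
                (7, 5),  # b2 = 7
                (7, 8),
                (8, 9),
                (9, 10),
                (10, 8),  # C
            ]
        )
        res = key_players(G, 2)
        assert res.selected == frozenset({3, 7})

    def test_deterministic(self):
        G = random_graph(np.random.default_rng(11), n_max=40)
        assert key_players(G, 3) == key_players(G, 3)


def test_node_metrics_table_and_writer(tmp_path):
    G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
    G.add_node(5)
    for v in G.nodes():
        G.nodes[v]["label"] = f"w{v}"
    rows = node_metrics_table(G)
    by_label = {r["label"]: r for r in rows}
    assert by_label["w0"] == {
        "label": "w0",
        "degree": 2,
        "clustering": 1.0,
        "component_class": "giant",
    }
    assert by_label["w5"]["component_class"] == "isolate"
    p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
    write_node_metrics(G, p1)
    write_node_metrics(G, p2)
    assert p1.read_bytes() == p2.read_bytes()
    header = p1.read_text(encoding="utf-8").splitlines()[0]
    assert header == "label\tdegree\tclustering\tcomponent_class"
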