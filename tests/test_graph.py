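"""Graph substrate: BFS distances, k-distance degrees, partitions, fixtures, I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leapdeg import (
    MolecularGraph,
    edge_partition,
    fixture_graph,
    k_distance_degrees,
    k_distance_degrees_oracle,
    read_edge_list,
    shortest_path_distances,
    write_edge_list,
)


class TestMolecularGraph:
    def test_rejects_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            MolecularGraph.from_edges(3, [(1, 1)])

    def test_rejects_out_of_range_endpoints(self):
        with pytest.raises(ValueError, match="invalid endpoint"):
            MolecularGraph.from_edges(3, [(0, 5)])

    def test_rejects_empty_vertex_set(self):
        with pytest.raises(ValueError):
            MolecularGraph.from_edges(0, [])

    def test_parallel_edges_collapse(self):
        g = MolecularGraph.from_edges(3, [(0, 1), (1, 0)])
        assert g.n_edges == 1


class TestShortestPathDistances:
    def test_path_graph_distances(self):
        g = fixture_graph("path", 4)
        assert shortest_path_distances(g, 0) == {0: 0, 1: 1, 2: 2, 3: 3}

    def test_cycle_opposite_vertex(self, c6):
        assert shortest_path_distances(c6, 0)[3] == 3

    def test_unreachable_vertices_absent(self):
        g = MolecularGraph.from_edges(4, [(0, 1), (2, 3)])
        dist = shortest_path_distances(g, 0)
        assert dist == {0: 0, 1: 1}
        assert 2 not in dist and 3 not in dist

    def test_invalid_source_raises(self, c6):
        with pytest.raises(ValueError, match="invalid source"):
            shortest_path_distances(c6, 17)


class TestKDistanceDegrees:
    @pytest.mark.parametrize(
        "kind,size,k,expected",
        [
            ("path", 4, 2, (1, 1, 1, 1)),
            ("cycle", 6, 2, (2, 2, 2, 2, 2, 2)),
            ("complete", 4, 2, (0, 0, 0, 0)),
            ("star", 4, 2, (0, 2, 2, 2)),  # center first, then leaves
            ("cycle", 6, 1, (2, 2, 2, 2, 2, 2)),
        ],
    )
    def test_known_small_graphs(self, kind, size, k, expected):
        g = fixture_graph(kind, size)
        assert k_distance_degrees(g, k).values == expected

    def test_k_below_one_raises(self, c6):
        with pytest.raises(ValueError):
            k_distance_degrees(c6, 0)

    def test_k1_equals_degree_sequence(self, small_fixtures):
        for g in small_fixtures.values():
            assert list(k_distance_degrees(g, 1).values) == g.degree_sequence()

    def test_matches_matrix_oracle_on_fixtures(self, small_fixtures, gnr11, zgnr3):
        for g in [*small_fixtures.values(), gnr11, zgnr3]:
            assert k_distance_degrees(g, 2) == k_distance_degrees_oracle(g)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), size=st.integers(2, 30))
    def test_matches_matrix_oracle_on_random_graphs(self, seed, size):
        g = fixture_graph("random", size, seed=seed)
        assert k_distance_degrees(g, 2) == k_distance_degrees_oracle(g)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), k=st.integers(1, 4))
    def test_degree_sum_is_even(self, seed, k):
        # each unordered pair at distance k is counted from both ends
        g = fixture_graph("random", 20, seed=seed)
        assert sum(k_distance_degrees(g, k).values) % 2 == 0

    def test_degrees_sum_to_component_sizes(self, small_fixtures):
        # summing deg_k over all k recovers (component size - 1) per vertex
        for g in small_fixtures.values():
            totals = [0] * g.n_vertices
            for k in range(1, g.n_vertices + 1):
                for v, d in enumerate(k_distance_degrees(g, k).values):
                    totals[v] += d
            for v in range(g.n_vertices):
                assert totals[v] == len(shortest_path_distances(g, v)) - 1


class TestEdgePartition:
    def test_cycle_single_class(self, c6):
        assert dict(edge_partition(c6, 2).classes) == {(2, 2): 6}

    def test_counts_sum_to_edge_count(self, small_fixtures):
        for g in small_fixtures.values():
            if g.n_edges:
                assert edge_partition(g, 2).n_edges == g.n_edges

    def test_gamma_ribbon_partition(self, gnr11):
        # cardinality polynomials evaluated at m = n = 1
        assert dict(edge_partition(gnr11, 2).classes) == {
            (2, 3): 12, (3, 5): 12, (5, 5): 6, (5, 6): 12, (6, 6): 12,
        }

    def test_zigzag_ribbon_partition(self, zgnr3):
        part = edge_partition(zgnr3, 2)
        assert dict(part.classes) == {
            (2, 2): 2, (2, 3): 8, (3, 3): 1, (3, 5): 10,
            (5, 5): 7, (5, 6): 6, (6, 6): 3,
        }
        assert part.n_edges == 37


class TestFixtureGraph:
    @pytest.mark.parametrize(
        "kind,size,nv,ne",
        [("cycle", 6, 6, 6), ("star", 4, 4, 3), ("path", 4, 4, 3), ("complete", 4, 4, 6)],
    )
    def test_sizes(self, kind, size, nv, ne):
        g = fixture_graph(kind, size)
        assert (g.n_vertices, g.n_edges) == (nv, ne)

    def test_random_is_reproducible(self):
        a = fixture_graph("random", 30, seed=7)
        b = fixture_graph("random", 30, seed=7)
        assert a.edges == b.edges

    def test_size_too_small_for_kind(self):
        with pytest.raises(ValueError):
            fixture_graph("cycle", 2)

    def test_random_without_seed_raises(self):
        with pytest.raises(ValueError, match="seed"):
            fixture_graph("random", 10)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            fixture_graph("torus", 10)


class TestEdgeListIO:
    def test_round_trip_preserves_graph(self, tmp_path, gnr11):
        path = tmp_path / "g.edgelist"
        write_edge_list(gnr11, path, header="gamma ribbon")
        back = read_edge_list(path)
        assert back.n_vertices == gnr11.n_vertices
        # labels are strings on read; compare canonical integer edge sets
        remap = {i: int(back.labels[i]) for i in range(back.n_vertices)}
        edges = frozenset(tuple(sorted((remap[u], remap[v]))) for u, v in back.edges)
        assert edges == gnr11.edges

    def test_comments_and_isolated_vertices(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("# a comment\na b\nc\n\nb d # trailing comment\n")
        g = read_edge_list(path)
        assert g.n_vertices == 4
        assert g.n_edges == 2
        assert g.degree_sequence().count(0) == 1

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("a b\nx y z\n")
        with pytest.raises(ValueError, match=":2:"):
            read_edge_list(path)

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "loop.txt"
        path.write_text("a a\n")
        with pytest.raises(ValueError, match=":1:"):
            read_edge_list(path)

    def test_writer_is_deterministic(self, tmp_path, zgnr3):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_edge_list(zgnr3, p1)
        write_edge_list(zgnr3, p2)
        assert p1.read_text() == p2.read_text()
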