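import networkx as nx
import pytest

import rigidscan as rs
from rigidscan.errors import ParseError, ValidationError


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadInteractions:
    def test_edge_list_basic(self, tmp_path):
        p = _write(tmp_path, "c1\t100\tc1\t200\t5\nc1\t200\tc1\t300\t2\nc1\t100\tc1\t300\t1\n")
        g = rs.read_interactions(p)
        assert (g.n, g.m) == (3, 3)

    def test_duplicate_rows_summed(self, tmp_path):
        p = _write(
            tmp_path,
            "c1\t100\tc1\t200\t5\nc1\t100\tc1\t200\t5\nc1\t200\tc1\t300\t2\n",
        )
        g = rs.read_interactions(p)
        u, v = rs.FragmentID("c1", 100), rs.FragmentID("c1", 200)
        assert g.graph[u][v]["frequency"] == 10

    def test_symmetric_pair_is_one_edge(self, tmp_path):
        p = _write(tmp_path, "c1\t100\tc1\t200\t5\nc1\t200\tc1\t100\t5\n")
        g = rs.read_interactions(p)
        assert g.m == 1
        assert g.graph[rs.FragmentID("c1", 100)][rs.FragmentID("c1", 200)]["frequency"] == 10

    def test_zero_frequency_and_self_pairs_dropped(self, tmp_path):
        p = _write(tmp_path, "c1\t100\tc1\t200\t0\nc1\t100\tc1\t100\t9\n")
        g = rs.read_interactions(p)
        assert g.m == 0

    def test_header_skipped(self, tmp_path):
        p = _write(tmp_path, "chrom1\tpos1\tchrom2\tpos2\tfrequency\nc1\t100\tc1\t200\t5\n")
        assert rs.read_interactions(p).m == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "c1\t100\tc1\t200\t5\nc1\tnope\tc1\t300\t2\n")
        with pytest.raises(ParseError, match="line 2"):
            rs.read_interactions(p)

    def test_negative_frequency_rejected(self, tmp_path):
        p = _write(tmp_path, "c1\t100\tc1\t200\t-3\n")
        with pytest.raises(ValidationError):
            rs.read_interactions(p)

    def test_dense_matrix(self, tmp_path):
        txt = (
            "\tc1:100\tc1:200\tc1:300\n"
            "c1:100\t0\t4\t0\n"
            "c1:200\t4\t0\t0\n"
            "c1:300\t0\t0\t0\n"
        )
        g = rs.read_interactions(_write(tmp_path, txt, "mat.tsv"), dialect="dense-matrix")
        assert (g.n, g.m) == (3, 1)  # all bins kept as vertices


def test_write_read_round_trip(tmp_path, fragment_line):
    g, frags, _ = fragment_line
    aug = rs.augment(g, frags)
    path = tmp_path / "out.tsv"
    rs.write_interactions(aug, path)
    back = rs.read_interactions(path)
    assert back.edges(data=True) == aug.edges(data=True)
    assert back.vertices() == aug.vertices()


class TestAugment:
    def test_backbone_closes_triangle(self, fragment_line):
        g, frags, (A, B, C, D, E) = fragment_line
        aug = rs.augment(g, frags)
        assert aug.graph.has_edge(B, C) and aug.graph.has_edge(C, D)
        assert all(aug.graph.has_edge(u, v) for u, v in ((B, C), (C, D), (B, D)))
        assert rs.is_rigid(aug.graph.subgraph([B, C, D])).rigid

    def test_unobserved_fragment_degree_two(self, fragment_line):
        g, frags, (*_, E) = fragment_line
        aug = rs.augment(g, frags)
        assert E in aug.graph
        assert aug.graph.degree(E) == 1  # chromosome end: a single backbone edge
        inner = rs.FragmentID("c1", 300)
        assert all(
            aug.graph.degree(f) <= 2
            for f in aug.graph
            if f not in g.graph or g.graph.degree(f) == 0
        )
        assert aug.graph[inner]

    def test_never_removes_and_flags_coincident(self, fragment_line):
        g, frags, (A, B, *_) = fragment_line
        aug = rs.augment(g, frags)
        for u, v in g.graph.edges:
            assert aug.graph.has_edge(u, v)
        # A-B is both measured and a backbone adjacency
        assert aug.graph[A][B]["frequency"] == 1.0
        assert aug.graph[A][B]["augmented"] is True

    def test_idempotent_when_adjacencies_measured(self):
        frags = rs.FragmentTable({"c1": [100, 200, 300]})
        g = rs.ConformationGraph.from_edges(
            [
                (rs.FragmentID("c1", 100), rs.FragmentID("c1", 200), 1.0),
                (rs.FragmentID("c1", 200), rs.FragmentID("c1", 300), 1.0),
            ]
        )
        aug = rs.augment(g, frags)
        assert aug.m == g.m and aug.n == g.n

    def test_missing_vertex_rejected(self):
        g = rs.ConformationGraph.from_edges(
            [(rs.FragmentID("c1", 100), rs.FragmentID("c1", 999), 1.0)]
        )
        with pytest.raises(ValidationError):
            rs.augment(g, rs.FragmentTable({"c1": [100, 200]}))

    def test_no_interchromosomal_backbone(self):
        frags = rs.FragmentTable({"c1": [100], "c2": [100]})
        g = rs.ConformationGraph.from_edges(
            [(rs.FragmentID("c1", 100), rs.FragmentID("c2", 100), 2.0)]
        )
        aug = rs.augment(g, frags)
        assert aug.m == 1 and not aug.graph[rs.FragmentID("c1", 100)][
            rs.FragmentID("c2", 100)
        ]["augmented"]


class TestPrune:
    def test_path_emptied(self):
        pruned, tris = rs.prune_low_degree(nx.path_graph(4))
        assert pruned.number_of_nodes() == 0 and tris == ()

    def test_pendant_removed_k4_kept(self):
        g = nx.complete_graph(4)
        g.add_edge(3, 9)
        pruned, tris = rs.prune_low_degree(g)
        assert sorted(pruned.nodes) == [0, 1, 2, 3] and tris == ()

    def test_isolated_triangle_recorded_and_rigid(self):
        g = nx.complete_graph(3)
        pruned, tris = rs.prune_low_degree(g)
        assert pruned.number_of_nodes() == 0
        assert tris == (frozenset({0, 1, 2}),)
        verdict = rs.is_rigid(g)
        assert verdict.rigid and verdict.rank == 3  # 3 = 3*3 - 6

    def test_single_sweep_vs_iterative(self):
        # 3-4-5 attaches to K4 through a path: one sweep leaves vertex 4
        g = nx.complete_graph(4)
        g.add_edges_from([(3, 4), (4, 5)])
        once, _ = rs.prune_low_degree(g, iterative=False)
        assert 4 not in once  # degree-2 vertex goes in the first sweep
        assert sorted(once.nodes) == [0, 1, 2, 3]

    def test_fragment_table_requires_sorted_centers(self):
        with pytest.raises(ValidationError):
            rs.FragmentTable({"c1": [300, 100]})
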