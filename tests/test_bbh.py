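import itertools

import networkx as nx
import pytest

import rigidscan as rs
from rigidscan.bbh import build_framework, grow_seed, merge_3_overlaps
from rigidscan.errors import ValidationError
from tests.conftest import random_graphs


class TestGrowSeed:
    def test_k5_grows_whole(self):
        grown = grow_seed(nx.complete_graph(5), used=set())
        assert grown == frozenset(range(5))

    def test_double_banana_one_banana_at_a_time(self, banana_graph):
        first = grow_seed(banana_graph, used=set())
        assert len(first) == 5 and {0, 1} <= first
        second = grow_seed(banana_graph, used=first,
                           seed_triangle=frozenset({0, 5, 6}))
        assert len(second) == 5 and first | second == set(range(8))

    def test_every_addition_keeps_rigidity(self):
        # slow debug property: replay growth one vertex at a time
        g = rs.isostatic_graph(10, seed=3)
        grown = grow_seed(g, used=set())
        assert grown == frozenset(g.nodes)
        order = sorted(grown)
        tri = grow_seed(g.subgraph(order), used=set())
        assert rs.is_rigid(g.subgraph(tri)).rigid

    def test_no_triangle_returns_none(self):
        assert grow_seed(nx.cycle_graph(5), used=set()) is None


class TestMerge3Overlaps:
    def test_shared_triangle_merges(self):
        a = frozenset({0, 1, 2, 3})
        b = frozenset({1, 2, 3, 4})
        assert merge_3_overlaps([a, b]) == [frozenset(range(5))]

    def test_shared_edge_untouched(self):
        a = frozenset({0, 1, 2, 3})
        b = frozenset({2, 3, 4, 5})
        assert sorted(merge_3_overlaps([a, b]), key=sorted) == [a, b]

    def test_transitive_closure(self):
        sets = [frozenset({0, 1, 2, 3}), frozenset({1, 2, 3, 4}), frozenset({2, 3, 4, 5})]
        for perm in itertools.permutations(sets):
            assert merge_3_overlaps(list(perm)) == [frozenset(range(6))]


class TestBuildFramework:
    def test_double_banana_one_hinge_no_bars(self, banana_graph):
        bodies = [frozenset({0, 1, 2, 3, 4}), frozenset({0, 1, 5, 6, 7})]
        framework, state = build_framework(bodies, banana_graph)
        assert len(state.hinges) == 1 and state.bars == []
        assert state.used_hinge_pairs == {frozenset({0, 1})}
        assert state.leftovers == []

    def test_bars_respect_endpoint_disjointness(self):
        # two disjoint K4 bodies joined by three candidate edges sharing vertex 0:
        # only one bar may touch vertex 0
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(range(4), 2))
        g.add_edges_from(itertools.combinations(range(4, 8), 2))
        g.add_edges_from([(0, 4), (0, 5), (1, 6)])
        bodies = [frozenset(range(4)), frozenset(range(4, 8))]
        framework, state = build_framework(bodies, g)
        assert state.hinges == []
        assert len(state.bars) == 2
        endpoints = sorted(state.used_nodes)
        assert len(endpoints) == 4  # no vertex carries two bars

    def test_single_vertex_overlap_goes_to_leftovers(self):
        bodies = [frozenset({0, 1, 2, 3}), frozenset({3, 4, 5, 6}), frozenset({7, 8, 9})]
        g = nx.Graph()
        g.add_nodes_from(range(10))
        framework, state = build_framework(bodies, g)
        assert frozenset({3, 4, 5, 6}) in state.leftovers
        assert len(state.reducible) == 2

    def test_three_plus_overlap_refused(self):
        with pytest.raises(ValidationError):
            build_framework([frozenset({0, 1, 2, 3}), frozenset({0, 1, 2, 4})], nx.Graph())


class TestBbhReduce:
    def test_double_banana_two_components(self, banana_graph):
        comps = rs.bbh_reduce(banana_graph)
        assert sorted(map(sorted, comps)) == [[0, 1, 2, 3, 4], [0, 1, 5, 6, 7]]

    def test_shared_vertex_triangles_passed_through(self, shared_vertex_triangles):
        comps = rs.bbh_reduce(shared_vertex_triangles)
        assert sorted(map(sorted, comps)) == [[0, 1, 2], [2, 3, 4]]

    def test_empty_graph(self):
        assert rs.bbh_reduce(nx.Graph()) == []

    def test_hinged_bodies_with_bar_merge(self):
        # two K5-minus-an-edge bodies sharing the missing edge's endpoints,
        # plus one independent cross edge: hinge + bar lock the two bodies
        g = rs.double_banana()
        g.add_edge(2, 5)
        comps = rs.bbh_reduce(g)
        assert comps == [frozenset(range(8))]
        assert rs.is_rigid(g).rigid

    def test_soundness_on_random_graphs(self):
        for g in random_graphs(40, base_seed=77):
            for comp in rs.bbh_reduce(g):
                verdict = rs.is_rigid(g.subgraph(comp))
                assert verdict.rigid, (sorted(comp), verdict)

    def test_components_within_oracle(self):
        for g in random_graphs(30, base_seed=99):
            oracle = rs.brute_force_components(g)
            for comp in rs.bbh_reduce(g):
                assert any(comp <= oc for oc in oracle)

    def test_modes_agree(self, banana_graph, shared_vertex_triangles):
        fixtures = [banana_graph, shared_vertex_triangles, nx.complete_graph(6),
                    rs.isostatic_graph(12, seed=5)]
        for g in fixtures + random_graphs(20, base_seed=13):
            assert set(rs.bbh_reduce(g, "any")) == set(rs.bbh_reduce(g, "max"))

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            rs.bbh_reduce(nx.Graph(), mode="fast")
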