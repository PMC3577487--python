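import pytest
from hypothesis import given, settings, strategies as st

import rigidscan as rs
from rigidscan.errors import ValidationError


def _chain_graph(freqs, chrom="c1", spacing=10_000):
    frs = [rs.FragmentID(chrom, (i + 1) * spacing) for i in range(len(freqs) + 1)]
    return rs.ConformationGraph.from_edges(
        [(frs[i], frs[i + 1], f) for i, f in enumerate(freqs)]
    )


class TestFrequencyFilter:
    def test_removes_lowest_percent(self):
        g = _chain_graph([1, 2, 3, 4, 5])
        out = rs.filter_frequency(g, 40)
        assert sorted(f for _, _, f in out.measured_edges()) == [3, 4, 5]
        assert out.n == g.n  # vertices retained even if isolated

    def test_zero_percent_identity(self):
        g = _chain_graph([1, 2, 3])
        assert rs.filter_frequency(g, 0).edges(data=True) == g.edges(data=True)

    def test_tied_frequencies_deterministic(self):
        g = _chain_graph([7] * 10)
        out1 = rs.filter_frequency(g, 50)
        out2 = rs.filter_frequency(g, 50)
        assert out1.m == 5
        assert out1.edges() == out2.edges()
        # documented tie rule: lexicographically smallest pairs removed first
        kept = out1.edges()
        doomed = sorted(set(g.edges()) - set(kept))
        assert doomed == sorted(g.edges())[:5]

    def test_out_of_range_percent(self):
        with pytest.raises(ValidationError):
            rs.filter_frequency(_chain_graph([1]), 101)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        freqs=st.lists(st.integers(1, 50), min_size=1, max_size=30),
        p1=st.floats(0, 100),
        p2=st.floats(0, 100),
    )
    def test_monotone_and_exact_count(self, freqs, p1, p2):
        import math

        g = _chain_graph(freqs)
        lo, hi = sorted((p1, p2))
        out_lo, out_hi = rs.filter_frequency(g, lo), rs.filter_frequency(g, hi)
        assert g.m - out_hi.m == math.floor(hi / 100 * g.m)
        assert set(out_hi.edges()) <= set(out_lo.edges())


class TestGenomicDistanceFilter:
    def test_short_span_removed(self):
        g = rs.ConformationGraph.from_edges(
            [(rs.FragmentID("c1", 10_000), rs.FragmentID("c1", 50_000), 3.0)]
        )
        assert rs.filter_genomic_distance(g, 75).m == 0

    def test_interchromosomal_retained(self):
        g = rs.ConformationGraph.from_edges(
            [(rs.FragmentID("c1", 10_000), rs.FragmentID("c2", 10_000), 3.0)]
        )
        assert rs.filter_genomic_distance(g, 1e6).m == 1

    def test_zero_cutoff_identity(self):
        g = _chain_graph([1, 2, 3])
        assert rs.filter_genomic_distance(g, 0).edges(data=True) == g.edges(data=True)


def _triangle(freqs):
    a, b, c = (rs.FragmentID("c1", 100 * (i + 1)) for i in range(3))
    return rs.ConformationGraph.from_edges(
        [(a, b, freqs[0]), (b, c, freqs[1]), (a, c, freqs[2])]
    )


class TestMetricFilter:
    def test_triangle_inequality_violation_removed(self):
        # inverse mapping gives weights 1, 1, 3: the long edge exceeds the 2-path
        g = _triangle([1.0, 1.0, 1.0 / 3.0])
        res = rs.filter_metric(g)
        assert res.graph.m == 2 and len(res.removed) == 1

    def test_boundary_equality_kept(self):
        g = _triangle([1.0, 1.0, 0.5])  # weights 1, 1, 2
        assert rs.filter_metric(g).graph.m == 3

    def test_equidistant_k5_all_kept(self):
        # the metric filter tests metric consistency, not 3D embeddability
        frs = [rs.FragmentID("c1", 100 * (i + 1)) for i in range(5)]
        import itertools

        g = rs.ConformationGraph.from_edges(
            [(u, v, 2.0) for u, v in itertools.combinations(frs, 2)]
        )
        assert rs.filter_metric(g).graph.m == 10

    def test_idempotent_and_closure_stable(self, toy_graph):
        res1 = rs.filter_metric(toy_graph)
        res2 = rs.filter_metric(res1.graph)
        assert res1.graph.edges() == res2.graph.edges()
        assert res2.removed == ()

    def test_vertex_preserving(self, toy_graph):
        assert rs.filter_metric(toy_graph).graph.n == toy_graph.n


class TestDistanceMapping:
    def test_inverse_is_decreasing(self):
        m = rs.DistanceMapping()
        assert m(10) < m(1)

    def test_user_table_must_decrease(self):
        with pytest.raises(ValidationError):
            rs.DistanceMapping(form="user_table", table=((1, 1.0), (2, 2.0)))

    def test_user_table_interpolates(self):
        m = rs.DistanceMapping(form="user_table", table=((1, 10.0), (3, 2.0)))
        assert m(2) == pytest.approx(6.0)
        assert m(0.5) == 10.0 and m(99) == 2.0

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValidationError):
            rs.DistanceMapping()(0)


def test_filter_spec_validation():
    with pytest.raises(ValidationError):
        rs.FilterSpec("frequency_percent", 150)
    with pytest.raises(ValidationError):
        rs.FilterSpec("genomic_distance_kb", -1)
    with pytest.raises(ValidationError):
        rs.FilterSpec("nonsense", 1)


def test_filters_compose_in_order(toy_graph):
    out = rs.apply_filters(
        toy_graph,
        [rs.FilterSpec("frequency_percent", 20), rs.FilterSpec("genomic_distance_kb", 20)],
    )
    assert out.n == toy_graph.n and out.m < toy_graph.m
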