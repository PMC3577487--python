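"""Preprocessing filters for conformation graphs.

Three schemes are supported, mirroring how conformation data is commonly
cleaned before an embedding is attempted:

1. frequency: remove the x% lowest-frequency interactions;
2. genomic distance: remove intra-chromosomal interactions spanning fewer
   than x kilobases (inter-chromosomal interactions are always kept);
3. metric: map frequencies to distances and keep only edges whose length
   equals the weighted shortest-path distance between their endpoints, so
   the retained set satisfies the shortest-path metric.

All filters preserve the vertex set, never add edges, and act on measured
edges only; backbone edges added by augmentation are left alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx

from .conformation import ConformationGraph
from .errors import ValidationError

#: relative tolerance when comparing an edge length with a shortest-path sum
METRIC_RTOL = 1e-9


@dataclass(frozen=True)
class DistanceMapping:
    """A strictly decreasing map from interaction frequency to spatial distance."""

    form: str = "inverse"  # inverse | inverse_power | user_table
    exponent: float = 1.0
    table: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.form not in ("inverse", "inverse_power", "user_table"):
            raise ValidationError(f"unknown mapping form {self.form!r}")
        if self.form == "user_table":
            pts = sorted(self.table)
            if len(pts) < 2 or any(
                d2 >= d1 for (_, d1), (_, d2) in zip(pts, pts[1:])
            ):
                raise ValidationError(
                    "user table must be strictly decreasing in frequency"
                )
            if any(d <= 0 or not math.isfinite(d) for _, d in pts):
                raise ValidationError("user table distances must be finite and positive")

    def __call__(self, frequency: float) -> float:
        if frequency <= 0:
            raise ValidationError("distance mapping requires a positive frequency")
        if self.form == "inverse":
            return 1.0 / frequency
        if self.form == "inverse_power":
            return frequency ** (-self.exponent)
        pts = sorted(self.table)
        # piecewise-linear interpolation, clamped at the ends
        if frequency <= pts[0][0]:
            return pts[0][1]
        for (f0, d0), (f1, d1) in zip(pts, pts[1:]):
            if frequency <= f1:
                t = (frequency - f0) / (f1 - f0)
                return d0 + t * (d1 - d0)
        return pts[-1][1]


@dataclass(frozen=True)
class FilterSpec:
    """One filtering step: kind plus its parameter."""

    kind: str  # frequency_percent | genomic_distance_kb | metric
    x: float = 0.0
    mapping: DistanceMapping = field(default_factory=DistanceMapping)

    def __post_init__(self):
        if self.kind == "frequency_percent" and not 0 <= self.x <= 100:
            raise ValidationError(f"percent {self.x} outside [0, 100]")
        if self.kind == "genomic_distance_kb" and self.x < 0:
            raise ValidationError(f"negative distance cutoff {self.x}")
        if self.kind not in ("frequency_percent", "genomic_distance_kb", "metric"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")


def _copy_without(g: ConformationGraph, doomed) -> ConformationGraph:
    out = g.copy()
    out.graph.remove_edges_from(doomed)
    return out


def filter_frequency(g: ConformationGraph, percent: float) -> ConformationGraph:
    """Remove the ``percent``% lowest-frequency measured interactions.

    Exactly floor(percent/100 * m) edges are removed, ordered by ascending
    frequency with lexicographic vertex-pair tie-breaking so the result is
    reproducible.  Vertices are kept even if they become isolated.
    """
    if not 0 <= percent <= 100:
        raise ValidationError(f"percent {percent} outside [0, 100]")
    measured = g.measured_edges()
    k = math.floor(percent / 100 * len(measured))
    doomed = sorted(measured, key=lambda e: (e[2], e[0], e[1]))[:k]
    return _copy_without(g, [(u, v) for u, v, _ in doomed])


def filter_genomic_distance(g: ConformationGraph, min_kb: float) -> ConformationGraph:
    """Remove intra-chromosomal measured interactions spanning < ``min_kb`` kilobases."""
    if min_kb < 0:
        raise ValidationError(f"negative distance cutoff {min_kb}")
    doomed = [
        (u, v)
        for u, v, _ in g.measured_edges()
        if u.chrom == v.chrom and abs(u.center - v.center) < min_kb * 1000
    ]
    return _copy_without(g, doomed)


class MetricFilterResult(NamedTuple):
    graph: ConformationGraph
    removed: tuple  # (u, v) pairs that violated the shortest-path metric


def filter_metric(
    g: ConformationGraph, mapping: DistanceMapping | None = None
) -> MetricFilterResult:
    """Keep the measured edges whose mapped length equals the shortest-path distance.

    Edge weights are ``mapping(frequency)``; an edge (u, v) survives iff its
    weight equals (within relative tolerance) the weighted shortest-path
    distance between u and v in the full weighted graph.  The retained set
    satisfies the shortest-path metric; backbone edges do not participate.
    """
    mapping = mapping or DistanceMapping()
    measured = g.measured_edges()
    weighted = nx.Graph()
    weighted.add_nodes_from(u for u, _, _ in measured)
    for u, v, f in measured:
        d = mapping(f)
        if d <= 0 or not math.isfinite(d):
            raise ValidationError(f"mapped distance {d} for frequency {f} is not positive")
        weighted.add_edge(u, v, weight=d)
    removed = []
    for u in weighted.nodes:
        dist = nx.single_source_dijkstra_path_length(weighted, u)
        for v in weighted[u]:
            if u < v:
                w = weighted[u][v]["weight"]
                if w > dist[v] * (1 + METRIC_RTOL):
                    removed.append((u, v))
    return MetricFilterResult(_copy_without(g, removed), tuple(sorted(removed)))


def apply_filter(g: ConformationGraph, spec: FilterSpec) -> ConformationGraph:
    if spec.kind == "frequency_percent":
        return filter_frequency(g, spec.x)
    if spec.kind == "genomic_distance_kb":
        return filter_genomic_distance(g, spec.x)
    return filter_metric(g, spec.mapping).graph


def apply_filters(g: ConformationGraph, specs) -> ConformationGraph:
    """Compose filters in the given order."""
    for spec in specs:
        g = apply_filter(g, spec)
    return g
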