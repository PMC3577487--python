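"""Synthetic graphs: rigidity-theory fixtures and polymer-like toy genomes.

These generators supply everything the analysis can be exercised on without
external data: the canonical double-banana counterexample, isostatic
(minimally rigid) growths, degree-preserving rewirings, and toy chromosome
conformation graphs with the short-range contact enrichment characteristic
of real conformation-capture data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .conformation import ConformationGraph, FragmentID, FragmentTable
from .errors import ValidationError


def double_banana() -> nx.Graph:
    """The 8-vertex, 18-edge double-banana graph.

    Two bananas (K5 minus one edge) share the endpoints {0, 1} of their
    missing edge.  The graph satisfies the 3n - 6 count on every subset yet
    is flexible: the bananas rotate about the implied hinge through the two
    shared (non-adjacent) vertices.  Vertices 2-4 form one banana with
    {0, 1}; vertices 5-7 the other.
    """
    g = nx.Graph()
    for wing in ((2, 3, 4), (5, 6, 7)):
        banana = (0, 1) + wing
        g.add_edges_from(
            (u, v) for u, v in itertools.combinations(banana, 2) if (u, v) != (0, 1)
        )
    return g


def isostatic_graph(n: int, seed: int = 0) -> nx.Graph:
    """A random minimally rigid graph on ``n`` vertices (exactly 3n - 6 edges).

    Built from a triangle by repeated vertex 3-addition: each new vertex is
    joined to three random existing vertices, which preserves rigidity, so
    the result is rigid and edge-minimal.
    """
    if n < 3:
        raise ValidationError("an isostatic graph needs at least 3 vertices")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (1, 2)])
    for v in range(3, n):
        for w in rng.choice(v, size=3, replace=False):
            g.add_edge(v, int(w))
    return g


def configuration_rewire(g, seed: int = 0, swaps_per_edge: int = 10) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two edges (a, b), (c, d) and rewires them to (a, d),
    (c, b) when that creates neither a self-loop nor a duplicate edge, so
    the output stays a simple graph with the input's exact degree sequence.
    Graphs admitting no valid swap (e.g. a triangle) are returned unchanged.
    """
    nxg = g.graph if isinstance(g, ConformationGraph) else g
    out = nx.Graph(nxg)
    m = out.number_of_edges()
    if m < 2:
        return out
    rng = np.random.default_rng(seed)
    target, tries, max_tries = swaps_per_edge * m, 0, 100 * swaps_per_edge * m
    done = 0
    edges = list(out.edges)
    while done < target and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    return out


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Parameters of a polymer-like toy conformation graph.

    Fragments are laid out evenly along each chromosome.  Intra-chromosomal
    pairs closer than ``short_range_span`` base pairs get an edge with
    probability ``short_range_rate`` (the short-range contact enrichment
    seen in real data); all other pairs, including inter-chromosomal ones,
    with probability ``long_range_rate``.  Frequencies are geometric-tailed
    positive integers whose mean decays with genomic distance.
    """

    n_chromosomes: int = 2
    fragments_per_chromosome: int = 60
    fragment_spacing: int = 10_000  # bp between consecutive fragment centers
    short_range_span: int = 50_000  # bp
    short_range_rate: float = 0.9
    long_range_rate: float = 0.01
    short_range_mean_frequency: float = 30.0
    long_range_mean_frequency: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.short_range_rate <= 1 and 0 <= self.long_range_rate <= 1):
            raise ValidationError("contact rates must be in [0, 1]")
        if self.short_range_span <= 0 or self.fragment_spacing <= 0:
            raise ValidationError("spans and spacings must be positive")
        if min(self.short_range_mean_frequency, self.long_range_mean_frequency) < 1:
            raise ValidationError("mean frequencies must be >= 1")

    def fragment_table(self) -> FragmentTable:
        return FragmentTable(
            {
                f"chr{c + 1}": [
                    (i + 1) * self.fragment_spacing
                    for i in range(self.fragments_per_chromosome)
                ]
                for c in range(self.n_chromosomes)
            }
        )


def toy_conformation_graph(spec: ToyGenomeSpec) -> ConformationGraph:
    """Generate a toy conformation graph; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    frags = list(spec.fragment_table().fragments())
    g = ConformationGraph()
    for f in frags:
        g.graph.add_node(f)
    lo, hi = spec.long_range_mean_frequency, spec.short_range_mean_frequency
    for u, v in itertools.combinations(frags, 2):
        intra = u.chrom == v.chrom
        d = abs(u.center - v.center) if intra else None
        short = intra and d < spec.short_range_span
        rate = spec.short_range_rate if short else spec.long_range_rate
        if rng.random() >= rate:
            continue
        mean = lo + (hi - lo) * float(np.exp(-d / spec.short_range_span)) if intra else lo
        freq = int(rng.geometric(1.0 / max(mean, 1.0)))
        g.add_interaction(u, v, float(freq))
    return g


def two_triangles_shared_vertex() -> nx.Graph:
    """Two triangles sharing one vertex: rigid components that no hinge can join."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)])
    return g


def fragment_graph(g: nx.Graph, chrom: str = "chr1", spacing: int = 10_000,
                   frequency: float = 1.0) -> ConformationGraph:
    """Relabel an abstract graph's integer vertices as fragments on one chromosome."""
    cg = ConformationGraph()
    nodes = sorted(g.nodes)
    lab = {v: FragmentID(chrom, (i + 1) * spacing) for i, v in enumerate(nodes)}
    for v in nodes:
        cg.graph.add_node(lab[v])
    for u, v in g.edges:
        cg.add_interaction(lab[u], lab[v], frequency)
    return cg
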