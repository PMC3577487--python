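"""Chromosome conformation graphs: data model, I/O, augmentation, pruning.

A conformation graph G = (V, E) has one vertex per genomic fragment center
(a ``FragmentID``) and one weighted edge per experimentally observed spatial
interaction; the weight is the observed interaction frequency.  An
*augmented* conformation graph additionally contains every fragment of the
genome (observed or not) and a backbone path of edges between genomically
adjacent fragments on each chromosome, modelling the linear chromatin fiber.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, NamedTuple

import networkx as nx

from .errors import ParseError, ValidationError


class FragmentID(NamedTuple):
    """A genomic fragment, identified by chromosome and fragment-center coordinate."""

    chrom: str
    center: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.center}"


class ConformationGraph:
    """A weighted interaction graph over genomic fragments.

    Wraps a :class:`networkx.Graph` whose nodes are :class:`FragmentID` and
    whose edges carry two attributes:

    ``frequency``
        observed interaction frequency (> 0 for measured edges, 0 for pure
        backbone edges added by :func:`augment`);
    ``augmented``
        True for backbone (genomic-adjacency) edges.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[FragmentID, FragmentID, float]],
        vertices: Iterable[FragmentID] = (),
    ) -> "ConformationGraph":
        """Build a graph from (u, v, frequency) triples.

        Self-pairs are dropped, duplicate pairs are summed, and
        zero-frequency entries are discarded.  Negative frequencies raise
        :class:`ValidationError`.
        """
        g = cls()
        for v in vertices:
            g.graph.add_node(_as_fragment(v))
        for u, v, f in edges:
            g.add_interaction(_as_fragment(u), _as_fragment(v), f)
        return g

    def add_interaction(self, u: FragmentID, v: FragmentID, frequency: float) -> None:
        if frequency < 0:
            raise ValidationError(f"negative frequency {frequency} for {u}--{v}")
        self.graph.add_node(u)
        self.graph.add_node(v)
        if u == v or frequency == 0:
            return
        if self.graph.has_edge(u, v):
            self.graph[u][v]["frequency"] += frequency
        else:
            self.graph.add_edge(u, v, frequency=float(frequency), augmented=False)

    def copy(self) -> "ConformationGraph":
        return ConformationGraph(self.graph.copy())

    # -- inspection ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def vertices(self) -> list[FragmentID]:
        return sorted(self.graph.nodes)

    def edges(self, data: bool = False):
        if data:
            return sorted(
                (tuple(sorted((u, v))) + (d["frequency"], d.get("augmented", False)))
                for u, v, d in self.graph.edges(data=True)
            )
        return sorted(tuple(sorted((u, v))) for u, v in self.graph.edges)

    def measured_edges(self) -> list[tuple[FragmentID, FragmentID, float]]:
        """Edges backed by an experimental observation (frequency > 0)."""
        return sorted(
            tuple(sorted((u, v))) + (d["frequency"],)
            for u, v, d in self.graph.edges(data=True)
            if d["frequency"] > 0
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ConformationGraph n={self.n} m={self.m}>"


class FragmentTable:
    """Per chromosome, the ordered centers of *all* fragments, observed or not."""

    def __init__(self, centers_by_chrom: dict[str, Iterable[int]]):
        self._centers: dict[str, list[int]] = {}
        for chrom, centers in centers_by_chrom.items():
            cs = list(centers)
            if sorted(set(cs)) != cs:
                raise ValidationError(
                    f"fragment centers for {chrom} must be strictly increasing"
                )
            self._centers[chrom] = cs

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._centers)

    def centers(self, chrom: str) -> list[int]:
        return list(self._centers[chrom])

    def __contains__(self, frag: FragmentID) -> bool:
        return frag.chrom in self._centers and frag.center in set(
            self._centers[frag.chrom]
        )

    def fragments(self) -> Iterator[FragmentID]:
        for chrom in self.chromosomes:
            for c in self._centers[chrom]:
                yield FragmentID(chrom, c)

    @classmethod
    def read(cls, path) -> "FragmentTable":
        """Read a fragment table from TSV: (chrom, center) or BED-like (chrom, start, end).

        For 3-column rows the fragment center is the interval midpoint
        (start + end) // 2.  A header row is skipped if its coordinate
        fields are non-numeric.
        """
        by_chrom: dict[str, list[int]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and not _is_int(parts[1]):
                    continue  # header
                try:
                    if len(parts) == 2:
                        chrom, center = parts[0], int(parts[1])
                    elif len(parts) >= 3:
                        chrom = parts[0]
                        center = (int(parts[1]) + int(parts[2])) // 2
                    else:
                        raise ValueError("expected 2 or 3 columns")
                except ValueError as exc:
                    raise ParseError(str(exc), line=lineno) from exc
                by_chrom.setdefault(chrom, []).append(center)
        return cls({c: sorted(set(v)) for c, v in by_chrom.items()})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["chrom1", "pos1", "chrom2", "pos2", "frequency", "augmented"]


def read_interactions(path, dialect: str = "edge-list") -> ConformationGraph:
    """Read a conformation graph from disk.

    ``edge-list`` rows are tab-separated (chrom1, pos1, chrom2, pos2,
    frequency) with an optional header and an optional sixth ``augmented``
    boolean column.  ``dense-matrix`` is a labelled square matrix of bin
    frequencies whose labels have the form ``chrom:center``.

    Duplicate pairs are summed, zero-frequency entries dropped, and
    self-pairs dropped; (u, v) and (v, u) are the same edge.
    """
    if dialect == "edge-list":
        return _read_edge_list(path)
    if dialect == "dense-matrix":
        return _read_dense_matrix(path)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_edge_list(path) -> ConformationGraph:
    g = ConformationGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and len(parts) >= 5 and not _is_int(parts[1]):
                continue  # header
            if len(parts) < 5:
                raise ParseError(
                    f"expected >= 5 tab-separated fields, got {len(parts)}", line=lineno
                )
            try:
                u = FragmentID(parts[0], int(parts[1]))
                v = FragmentID(parts[2], int(parts[3]))
                freq = float(parts[4])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            augmented = len(parts) > 5 and parts[5].strip().lower() in ("1", "true")
            if freq < 0:
                raise ValidationError(f"line {lineno}: negative frequency {freq}")
            if u == v:
                continue
            if augmented and freq == 0:
                # pure backbone edge from a previous write
                g.graph.add_edge(u, v, frequency=0.0, augmented=True)
                continue
            if freq == 0:
                continue
            g.add_interaction(u, v, freq)
            if augmented:
                g.graph[u][v]["augmented"] = True
    return g


def _read_dense_matrix(path) -> ConformationGraph:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("dense matrix row and column labels differ")
    labels = []
    for lab in df.index:
        try:
            chrom, center = str(lab).rsplit(":", 1)
            labels.append(FragmentID(chrom, int(center)))
        except ValueError as exc:
            raise ParseError(f"bin label {lab!r} is not 'chrom:center'") from exc
    mat = df.to_numpy(dtype=float)
    if not (abs(mat - mat.T) <= 1e-9 * (1 + abs(mat))).all():
        raise ValidationError("dense matrix is not symmetric")
    if (mat < 0).any():
        raise ValidationError("dense matrix has negative frequencies")
    g = ConformationGraph()
    for lab in labels:
        g.graph.add_node(lab)
    k = len(labels)
    for i in range(k):
        for j in range(i + 1, k):
            if mat[i, j] > 0:
                g.add_interaction(labels[i], labels[j], mat[i, j])
    return g


def write_interactions(g: ConformationGraph, path) -> None:
    """Write the edge-list dialect, with the ``augmented`` boolean column."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for u, v, freq, aug in g.edges(data=True):
            fh.write(
                f"{u.chrom}\t{u.center}\t{v.chrom}\t{v.center}\t{freq:g}\t"
                f"{'true' if aug else 'false'}\n"
            )


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _as_fragment(v) -> FragmentID:
    return v if isinstance(v, FragmentID) else FragmentID(*v)


# ---------------------------------------------------------------------------
# Augmentation and pruning
# ---------------------------------------------------------------------------


def augment(g: ConformationGraph, frags: FragmentTable) -> ConformationGraph:
    """Add the linear-chromatin backbone to a conformation graph.

    The result contains every fragment of ``frags`` (including fragments
    with no observed interaction) and, per chromosome, an edge between each
    pair of genomically consecutive fragments.  Measured edges are kept
    untouched; a backbone edge that coincides with a measured edge keeps the
    measured frequency and gains the ``augmented`` flag.  Backbone edges
    carry no frequency semantics (frequency 0): they are pure distance
    constraints.
    """
    for v in g.graph.nodes:
        if v not in frags:
            raise ValidationError(f"vertex {v} missing from the fragment table")
    out = g.copy()
    for chrom in frags.chromosomes:
        centers = frags.centers(chrom)
        for c in centers:
            out.graph.add_node(FragmentID(chrom, c))
        for a, b in itertools.pairwise(centers):
            u, v = FragmentID(chrom, a), FragmentID(chrom, b)
            if out.graph.has_edge(u, v):
                out.graph[u][v]["augmented"] = True
            else:
                out.graph.add_edge(u, v, frequency=0.0, augmented=True)
    return out


class PruneResult(NamedTuple):
    graph: ConformationGraph
    rigid_triangles: tuple[frozenset, ...]


def prune_low_degree(g: ConformationGraph, iterative: bool = True) -> PruneResult:
    """Remove vertices of degree <= 2; they cannot join rigid components of size >= 4.

    With ``iterative=True`` (default) the sweep repeats to a fixed point
    (the 3-core); otherwise a single sweep is performed.  Triangles that
    contain a pruned vertex are genuine size-3 rigid components that the
    sweep would silently destroy (a pruned vertex can never belong to a
    rigid component of 4 or more vertices, so such a triangle is maximal);
    they are recorded and returned alongside the pruned graph.
    """
    nxg = g.graph if isinstance(g, ConformationGraph) else g
    work = nx.Graph(nxg)
    removed: set = set()
    while True:
        low = [v for v, d in work.degree if d <= 2]
        if not low:
            break
        removed.update(low)
        work.remove_nodes_from(low)
        if not iterative:
            break
    triangles = set()
    for v in removed:
        nbrs = sorted(nxg.neighbors(v))
        for a, b in itertools.combinations(nbrs, 2):
            if nxg.has_edge(a, b):
                triangles.add(frozenset((v, a, b)))
    pruned = nx.Graph(nxg.subgraph([v for v in nxg if v not in removed]))
    if isinstance(g, ConformationGraph):
        return PruneResult(ConformationGraph(pruned), tuple(sorted(triangles, key=sorted)))
    return PruneResult(pruned, tuple(sorted(triangles, key=sorted)))
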