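"""Generic rigidity testing via rank of the rigidity matrix.

A graph of distance constraints with vertex positions p in R^d has an
m x (d n) rigidity matrix with one row per edge (u, v): the row carries
(p_u - p_v) in u's column block, (p_v - p_u) in v's column block, and zeros
elsewhere.  For a generic embedding the rank of this matrix depends only on
the graph; a graph on n >= d vertices is rigid in R^d iff the generic rank
equals d*n - d(d+1)/2 (3n - 6 in three dimensions).  A random embedding is
generic with overwhelming probability, so rigidity is tested by sampling a
few random embeddings and taking the maximum observed rank.

Two rank backends are provided: an exact one over a large prime field with
random integer coordinates (the default; immune to floating-point
tolerance), and a floating-point singular-value backend.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError

#: modulus for exact rank computation (Mersenne prime 2^31 - 1); products of
#: two residues fit in int64.
_PRIME = 2**31 - 1


def _as_nx(g) -> nx.Graph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.Graph) else g


def max_generic_rank(n: int, dim: int = 3) -> int:
    """Largest possible rigidity-matrix rank for n vertices in R^dim.

    d*n - d(d+1)/2 once n >= d; for fewer vertices the complete graph bound
    n(n-1)/2 applies (a single edge on two vertices has rank 1).
    """
    return min(n * (n - 1) // 2, dim * n - dim * (dim + 1) // 2)


def random_embedding(vertices, seed: int = 0, dim: int = 3, integer: bool = True):
    """Random generic positions for each vertex: integers in [1, p) or floats."""
    rng = np.random.default_rng(seed)
    vs = sorted(vertices)
    if integer:
        coords = rng.integers(1, _PRIME, size=(len(vs), dim), dtype=np.int64)
    else:
        coords = rng.standard_normal((len(vs), dim))
    return {v: tuple(coords[i]) for i, v in enumerate(vs)}


@dataclass
class RigidityMatrix:
    """The rigidity matrix of a graph at a fixed embedding."""

    matrix: np.ndarray
    vertices: list
    edges: list
    exact: bool
    dim: int = 3

    @property
    def rank(self) -> int:
        if self.matrix.size == 0:
            return 0
        if self.exact:
            return _rank_mod_p(self.matrix % _PRIME)
        return _rank_float(self.matrix)


def rigidity_matrix(g, emb: dict, dim: int = 3) -> RigidityMatrix:
    """Build the m x (dim*n) rigidity matrix of ``g`` at embedding ``emb``."""
    nxg = _as_nx(g)
    vs = sorted(nxg.nodes)
    for v in vs:
        if v not in emb:
            raise ValidationError(f"embedding is missing vertex {v}")
    idx = {v: i for i, v in enumerate(vs)}
    edges = sorted(tuple(sorted((u, v))) for u, v in nxg.edges)
    exact = all(
        all(isinstance(c, (int, np.integer)) for c in emb[v]) for v in vs
    )
    dtype = np.int64 if exact else np.float64
    M = np.zeros((len(edges), dim * len(vs)), dtype=dtype)
    for r, (u, v) in enumerate(edges):
        pu = np.asarray(emb[u], dtype=dtype)
        pv = np.asarray(emb[v], dtype=dtype)
        d = pu - pv if not exact else (pu - pv) % _PRIME
        M[r, dim * idx[u] : dim * idx[u] + dim] = d
        M[r, dim * idx[v] : dim * idx[v] + dim] = (-d) % _PRIME if exact else -d
    return RigidityMatrix(M, vs, edges, exact, dim)


def _rank_mod_p(M: np.ndarray) -> int:
    """Rank over GF(p) by vectorized Gaussian elimination."""
    A = (M % _PRIME).astype(np.int64).copy()
    rows, cols = A.shape
    rank = 0
    for c in range(cols):
        if rank == rows:
            break
        piv = np.nonzero(A[rank:, c])[0]
        if piv.size == 0:
            continue
        r = rank + piv[0]
        if r != rank:
            A[[rank, r]] = A[[r, rank]]
        inv = pow(int(A[rank, c]), _PRIME - 2, _PRIME)
        A[rank] = (A[rank] * inv) % _PRIME
        below = A[rank + 1 :, c] != 0
        if below.any():
            rows_below = np.nonzero(below)[0] + rank + 1
            factors = A[rows_below, c][:, None]
            A[rows_below] = (A[rows_below] - factors * A[rank][None, :]) % _PRIME
        rank += 1
    return rank


def _rank_float(M: np.ndarray) -> int:
    s = np.linalg.svd(np.asarray(M, dtype=float), compute_uv=False)
    if s.size == 0:
        return 0
    return int((s > 1e-8 * s[0]).sum())


def generic_rank(
    g, trials: int = 3, seed: int = 0, dim: int = 3, backend: str = "exact"
) -> int:
    """Generic rank of the rigidity matrix: max over random embeddings."""
    nxg = _as_nx(g)
    if nxg.number_of_edges() == 0:
        return 0
    best = 0
    bound = min(nxg.number_of_edges(), max_generic_rank(nxg.number_of_nodes(), dim))
    for t in range(trials):
        emb = random_embedding(
            nxg.nodes, seed=seed + t, dim=dim, integer=(backend == "exact")
        )
        best = max(best, rigidity_matrix(nxg, emb, dim).rank)
        if best == bound:
            break
    return best


@dataclass(frozen=True)
class RigidityVerdict:
    """Outcome of a generic rigidity test."""

    rigid: bool
    dof: int  # internal degrees of freedom: max_generic_rank - rank
    rank: int
    n: int
    m: int
    trials_used: int

    def summary(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "rank": self.rank,
            "dof": self.dof,
            "rigid": self.rigid,
        }


def is_rigid(
    g, trials: int = 3, seed: int = 0, dim: int = 3, backend: str = "exact"
) -> RigidityVerdict:
    """Test generic rigidity of ``g`` in R^dim by random-embedding rank tests.

    Graphs on one or two vertices are trivially rigid by convention and are
    reported as such without a rank test.
    """
    nxg = _as_nx(g)
    n, m = nxg.number_of_nodes(), nxg.number_of_edges()
    if n == 0:
        raise ValidationError("rigidity of the empty graph is undefined")
    if n <= 2:
        return RigidityVerdict(True, 0, m, n, m, 0)
    target = max_generic_rank(n, dim)
    rank = generic_rank(nxg, trials=trials, seed=seed, dim=dim, backend=backend)
    return RigidityVerdict(rank == target, target - rank, rank, n, m, trials)


def excess_edge_count(n: int, m: int, dim: int = 3) -> int:
    """Edges beyond the minimum needed for rigidity: m - (d*n - d(d+1)/2)."""
    return m - (dim * n - dim * (dim + 1) // 2)


def brute_force_components(
    g, guard: int = 12, seed: int = 0, dim: int = 3, backend: str = "exact"
):
    """All maximal rigid vertex subsets (size >= 3) by exhaustive rank testing.

    Enumerates induced subgraphs in decreasing size and keeps every rigid
    subset not contained in a larger kept subset.  Exponential: refuses
    graphs above ``guard`` vertices unless the guard is raised.
    """
    nxg = _as_nx(g)
    vs = sorted(nxg.nodes)
    n = len(vs)
    if n > guard:
        raise ValidationError(
            f"brute force on {n} vertices exceeds the guard ({guard}); "
            "raise `guard` explicitly to override"
        )
    found: list[frozenset] = []
    for size in range(n, 2, -1):
        for subset in itertools.combinations(vs, size):
            sset = frozenset(subset)
            if any(sset <= f for f in found):
                continue
            sub = nxg.subgraph(subset)
            if sub.number_of_edges() < max_generic_rank(size, dim):
                continue
            if size >= 4 and min(d for _, d in sub.degree) < dim:
                continue
            if is_rigid(sub, trials=2, seed=seed, dim=dim, backend=backend).rigid:
                found.append(sset)
    return sorted(found, key=lambda s: (-len(s), sorted(s)))
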