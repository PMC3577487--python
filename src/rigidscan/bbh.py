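"""Body-bar-and-hinge reduction: rigid components from glued rigid seeds.

The reduction builds provably rigid subgraphs bottom-up and then merges
them through an exact body-bar-and-hinge computation:

1. vertices of degree <= 2 are peeled away (they cannot join a rigid
   component of 4 or more vertices); triangles destroyed by the peeling are
   kept as size-3 components;
2. seed triangles are grown one vertex at a time, each new vertex having at
   least three edges into the current subgraph (vertex 3-addition keeps the
   subgraph rigid);
3. grown subgraphs sharing >= 3 vertices are unioned (generic 3-gluing
   keeps the union rigid);
4. the surviving subgraphs become rigid *bodies*; pairs of bodies sharing
   exactly two vertices are joined by a hinge, and graph edges running
   between bodies become bars, subject to the rule that no vertex carries
   two bars or a bar and a hinge; the exact (6, 6) pebble game on this
   body-bar-and-hinge multigraph merges bodies that are mutually rigid.

Every returned vertex set is rigid, but the sets need not be maximal: some
bar-joint structures (e.g. two triangles sharing a single vertex) have no
body-bar-and-hinge representation and are passed through unmerged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .conformation import prune_low_degree
from .errors import ValidationError
from .pebble import BodyBarHingeMultigraph, body_bar_components


def _as_nx(g) -> nx.Graph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.Graph) else g


@dataclass
class ReductionState:
    """Bookkeeping of one body-bar-and-hinge reduction."""

    bodies: list  # R: rigid vertex sets after 3-gluing
    reducible: list  # R2: subset with pairwise overlap 0 or 2
    leftovers: list  # R \ R2
    hinges: list = field(default_factory=list)  # H: pairs of body indices
    bars: list = field(default_factory=list)  # B: vertex pairs
    used_hinge_pairs: set = field(default_factory=set)  # U_H
    used_nodes: set = field(default_factory=set)  # U_N


# ---------------------------------------------------------------------------
# seed growth
# ---------------------------------------------------------------------------


def _triangles(g: nx.Graph):
    for u, v in g.edges:
        for w in g[u]:
            if w != v and g.has_edge(w, v):
                yield frozenset((u, v, w))


def _degree_excluding(g: nx.Graph, v, used: set) -> int:
    return sum(1 for w in g[v] if w not in used)


def _pick_seed(g: nx.Graph, components: list, used: set, mode: str):
    """A triangle not fully contained in any existing component, per mode."""
    best = None
    best_key = None
    for t in set(_triangles(g)):
        if any(t <= c for c in components):
            continue
        tk = tuple(sorted(t))
        if mode == "any":
            key = tk
            if best_key is None or key < best_key:
                best, best_key = t, key
        else:  # max: largest total degree excluding edges incident to `used`
            deg = sum(_degree_excluding(g, v, used) for v in tk)
            key = (-deg, tk)
            if best_key is None or key < best_key:
                best, best_key = t, key
    return best


def grow_seed(g, used, mode: str = "any", seed_triangle=None):
    """Grow a rigid vertex set from a triangle by repeated vertex 3-addition.

    Each added vertex has at least three edges into the current set, so the
    grown set stays rigid.  ``max`` mode adds the eligible vertex of highest
    degree (edges to ``used`` vertices not counted); ``any`` adds the first
    in sorted order.  Returns None when no eligible seed triangle exists.
    """
    nxg = _as_nx(g)
    used = set(used)
    if seed_triangle is None:
        seed_triangle = _pick_seed(nxg, [], used, mode)
        if seed_triangle is None:
            return None
    grown = set(seed_triangle)
    while True:
        eligible = [
            v
            for v in nxg.nodes
            if v not in grown and sum(1 for w in nxg[v] if w in grown) >= 3
        ]
        if not eligible:
            break
        if mode == "max":
            v = min(eligible, key=lambda x: (-_degree_excluding(nxg, x, used), x))
        else:
            v = min(eligible)
        grown.add(v)
    return frozenset(grown)


def merge_3_overlaps(bodies) -> list:
    """Union members sharing >= 3 vertices until none do (3-gluing closure).

    Overlap only grows under union, so the fixed point is order-independent.
    """
    work = [frozenset(b) for b in bodies]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(work)), 2):
            if len(work[i] & work[j]) >= 3:
                merged = work[i] | work[j]
                work = [c for idx, c in enumerate(work) if idx not in (i, j)]
                work.append(merged)
                changed = True
                break
    return sorted(set(work), key=lambda c: (-len(c), sorted(c)))


# ---------------------------------------------------------------------------
# framework construction
# ---------------------------------------------------------------------------


def build_framework(bodies, g) -> tuple[BodyBarHingeMultigraph, ReductionState]:
    """Reduce rigid bodies plus the constraint graph to a body-bar-and-hinge framework.

    Bodies must pairwise overlap by at most two vertices (3-overlaps are
    merged beforehand).  A greedy pass (largest body first) selects the
    subset whose pairwise overlaps are exactly 0 or 2; each 2-overlap pair
    whose shared vertex pair is still unused becomes a hinge, then edges of
    ``g`` running between body-exclusive vertices become bars, no vertex
    carrying more than one bar or a bar plus a hinge.
    """
    nxg = _as_nx(g)
    bodies = sorted((frozenset(b) for b in bodies), key=lambda c: (-len(c), sorted(c)))
    for a, b in itertools.combinations(bodies, 2):
        if len(a & b) >= 3:
            raise ValidationError("bodies overlapping by >= 3 vertices must be merged first")
    reducible: list[frozenset] = []
    leftovers: list[frozenset] = []
    for cand in bodies:
        if all(len(cand & other) in (0, 2) for other in reducible):
            reducible.append(cand)
        else:
            leftovers.append(cand)
    state = ReductionState(bodies=bodies, reducible=reducible, leftovers=leftovers)

    idx = {b: i for i, b in enumerate(reducible)}
    pairs = list(itertools.combinations(reducible, 2))
    # hinges first, larger pairs first: a hinge carries 5 constraints
    for ci, cj in sorted(pairs, key=lambda p: (-(len(p[0]) + len(p[1])),
                                               sorted(p[0]), sorted(p[1]))):
        shared = ci & cj
        if len(shared) == 2 and frozenset(shared) not in state.used_hinge_pairs:
            state.hinges.append((idx[ci], idx[cj]))
            state.used_hinge_pairs.add(frozenset(shared))
            state.used_nodes.update(shared)
    # then bars, scanning candidate vertex pairs in lexicographic order
    bar_edges = []
    for ci, cj in pairs:
        for v in sorted(ci - cj):
            for w in sorted(cj - ci):
                if nxg.has_edge(v, w):
                    bar_edges.append((tuple(sorted((v, w))), idx[ci], idx[cj]))
    for (v, w), i, j in sorted(bar_edges):
        if v in state.used_nodes or w in state.used_nodes:
            continue
        state.bars.append((i, j))
        state.used_nodes.update((v, w))
    framework = BodyBarHingeMultigraph(
        bodies=list(range(len(reducible))),
        hinges=state.hinges,
        bars=state.bars,
    )
    return framework, state


# ---------------------------------------------------------------------------
# full reduction
# ---------------------------------------------------------------------------


def bbh_reduce(g, mode: str = "any") -> list[frozenset]:
    """Find rigid components by seed growth, 3-gluing and body-bar-and-hinge merging.

    Returns vertex sets (size >= 3), each generically rigid in 3D; the sets
    may be non-maximal.  ``mode`` selects how seed triangles and added
    vertices are chosen: ``any`` (first in deterministic order; default) or
    ``max`` (highest degree first).
    """
    if mode not in ("any", "max"):
        raise ValidationError(f"unknown mode {mode!r}")
    nxg = _as_nx(g)
    core, rescued_triangles = prune_low_degree(nxg, iterative=True)

    bodies: list[frozenset] = []
    while True:
        used = set().union(*bodies) if bodies else set()
        seed = _pick_seed(core, bodies, used, mode)
        if seed is None:
            break
        bodies.append(grow_seed(core, used, mode=mode, seed_triangle=seed))
        bodies = merge_3_overlaps(bodies)
    bodies = merge_3_overlaps(bodies)

    framework, state = build_framework(bodies, core)
    body_sets = body_bar_components(framework)
    comps: list[frozenset] = []
    for bset in body_sets:
        comps.append(frozenset().union(*(state.reducible[i] for i in bset)))
    comps.extend(state.leftovers)
    comps.extend(rescued_triangles)
    # drop components contained in another
    comps = sorted(set(comps), key=lambda c: (-len(c), sorted(c)))
    kept: list[frozenset] = []
    for c in comps:
        if len(c) >= 3 and not any(c <= k for k in kept):
            kept.append(c)
    return kept
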