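"""Hybrid rigid-component finder and rigidity sweeps.

The finder combines the fast (3, 6) pebble-game heuristic with exact rank
verification: per connected component, pebble candidates that pass the rank
test are reported directly; floppy candidates (the pebble game can merge
distinct rigid components across an implied hinge) are decomposed by the
body-bar-and-hinge reduction.  Every reported component is rank-verified,
so a floppy set is never reported as rigid, though reported components need
not be maximal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .bbh import bbh_reduce, _triangles
from .conformation import ConformationGraph
from .filtering import FilterSpec, apply_filter
from .pebble import PebbleGame, pebble_components
from .rigidity import RigidityVerdict, is_rigid


def _as_nx(g) -> nx.Graph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.Graph) else g


@dataclass(frozen=True)
class RigidComponent:
    """A reported rigid component: vertex set, rank-test verdict, provenance."""

    vertices: frozenset
    verified: RigidityVerdict
    provenance: str  # pebble_verified | bbh_reduced | isolated_triangle | trivial

    @property
    def size(self) -> int:
        return len(self.vertices)


def find_rigid_components(
    g,
    mode: str = "any",
    seed: int = 0,
    trials: int = 3,
    backend: str = "exact",
    include_trivial: bool = False,
) -> list[RigidComponent]:
    """All rigid components found by the hybrid pebble + reduction strategy.

    Rigid components are sought inside connected components (they never span
    them).  Pebble candidates failing the rank test are decomposed with
    :func:`rigidscan.bbh.bbh_reduce`; finally, triangles not covered by any
    reported component are reported as size-3 components (any triangle is
    rigid, and one the main pass missed can only be maximal or inside a
    component the pass also missed).  Components of size 1-2 are suppressed
    unless ``include_trivial`` is set.
    """
    nxg = _as_nx(g)
    sets: list[tuple[frozenset, str]] = []
    for cc in nx.connected_components(nxg):
        if len(cc) < 3:
            continue
        sub = nxg.subgraph(cc)
        for cand in pebble_components(sub, 3, 6):
            cand_sub = nxg.subgraph(cand)
            if is_rigid(cand_sub, trials=trials, seed=seed, backend=backend).rigid:
                sets.append((cand, "pebble_verified"))
            else:
                for c in bbh_reduce(cand_sub, mode=mode):
                    sets.append((c, "bbh_reduced"))
    covered = [s for s, _ in sets]
    for t in sorted(set(_triangles(nxg)), key=sorted):
        if not any(t <= c for c in covered):
            sets.append((t, "isolated_triangle"))

    # drop components contained in another reported component
    sets.sort(key=lambda sp: (-len(sp[0]), sorted(sp[0])))
    kept: list[tuple[frozenset, str]] = []
    for s, prov in sets:
        if not any(s <= k for k, _ in kept):
            kept.append((s, prov))

    comps = [
        RigidComponent(s, is_rigid(nxg.subgraph(s), trials=trials, seed=seed,
                                   backend=backend), prov)
        for s, prov in kept
    ]
    if include_trivial:
        in_comp = set().union(*(c.vertices for c in comps)) if comps else set()
        for u, v in sorted(tuple(sorted(e)) for e in nxg.edges):
            if u not in in_comp or v not in in_comp:
                pair = frozenset((u, v))
                if not any(pair <= c.vertices for c in comps):
                    comps.append(
                        RigidComponent(pair, RigidityVerdict(True, 0, 1, 2, 1, 0), "trivial")
                    )
        for v in nxg.nodes:
            if nxg.degree(v) == 0:
                comps.append(
                    RigidComponent(frozenset((v,)), RigidityVerdict(True, 0, 0, 1, 0, 0),
                                   "trivial")
                )
    comps.sort(key=lambda c: (-c.size, sorted(c.vertices)))
    return comps


# ---------------------------------------------------------------------------
# minimally rigid subgraph sampling
# ---------------------------------------------------------------------------


class MinimalRigidSample(NamedTuple):
    accepted: frozenset  # independent edge set accepted by the pebble game
    components: tuple  # (vertex frozenset, edge frozenset) per detected component


def sample_minimally_rigid(g, n_samples: int, seed: int = 0) -> list[MinimalRigidSample]:
    """Sample minimally rigid (independent) edge subsets via random edge orders.

    Each sample shuffles the edge insertion order of the (3, 6) pebble game
    with a per-sample seed; the accepted edges form an independent set (no
    redundant constraints), reported both globally and restricted to each
    detected candidate component.
    """
    from .errors import ValidationError

    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    nxg = _as_nx(g)
    edges = sorted(tuple(sorted((u, v))) for u, v in nxg.edges)
    samples = []
    for i in range(n_samples):
        rng = np.random.default_rng((seed, i))
        order = [edges[j] for j in rng.permutation(len(edges))]
        game = PebbleGame(sorted(nxg.nodes), 3, 6)
        res = game.run(order)
        accepted = frozenset(frozenset(e) for e in res.accepted)
        comps = tuple(
            (c, frozenset(e for e in accepted if e <= c))
            for c in res.components
            if len(c) >= 3
        )
        samples.append(MinimalRigidSample(accepted, comps))
    return samples


# ---------------------------------------------------------------------------
# filter sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepPoint:
    """Rigidity profile of the graph after one grid point's filters."""

    filters: tuple[FilterSpec, ...]
    sizes: tuple[int, ...]  # component sizes, descending
    largest: int
    total: int  # sum of component sizes
    assignment: dict  # vertex -> component index (shared vertices go to the larger)


def sweep(g: ConformationGraph, filter_grid, **finder_kwargs) -> list[SweepPoint]:
    """Apply each grid point's filter(s), find rigid components, and profile them.

    ``filter_grid`` is an iterable whose items are a FilterSpec or a tuple
    of FilterSpecs applied in order.  A vertex in several (overlapping)
    components is assigned to the largest one; unassigned vertices map to -1.
    """
    points = []
    for item in filter_grid:
        specs = tuple(item) if isinstance(item, (tuple, list)) else (item,)
        filtered = g
        for spec in specs:
            filtered = apply_filter(filtered, spec)
        comps = find_rigid_components(filtered, **finder_kwargs)
        sizes = tuple(c.size for c in comps)
        assignment = {v: -1 for v in _as_nx(g).nodes}
        for i, c in enumerate(comps):  # comps sorted by decreasing size
            for v in c.vertices:
                if assignment.get(v, -1) == -1:
                    assignment[v] = i
        points.append(
            SweepPoint(specs, sizes, max(sizes, default=0), sum(sizes), assignment)
        )
    return points


def sweep_frame(points):
    """Long-format table (grid point, component rank, size) for plotting."""
    import pandas as pd

    rows = []
    for i, p in enumerate(points):
        label = "+".join(f"{s.kind}={s.x:g}" for s in p.filters)
        if not p.sizes:
            rows.append((i, label, -1, 0))
        for rank_, size in enumerate(p.sizes):
            rows.append((i, label, rank_, size))
    return pd.DataFrame(rows, columns=["grid_point", "filters", "component_rank", "size"])
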