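"""Generic (k, l) pebble games with rigid-component detection.

Two rule variants are implemented behind one state machine:

* the standard sparsity game for l < 2k (Lee & Streinu): an edge is
  accepted when l + 1 pebbles can be gathered on its endpoints.  With
  (2, 3) on simple graphs this finds exact 2D rigid components; with
  (6, 6) on body-bar-and-hinge multigraphs (a hinge contributing 5
  parallel edges, a bar 1) it finds exact body-level rigid components by
  Tay's theorem.

* the 3D bar-joint variant with (k, l) = (3, 6), where l + 1 = 7 pebbles
  exceed the 2k = 6 that two endpoints can hold.  An edge is accepted when
  k pebbles sit on each endpoint and either a seventh free pebble is
  reachable or the endpoints reach nothing else (a bare pair, whose count
  bound does not apply).  This enforces the 3n - 6 count on every subset of
  >= 3 vertices.  The count is necessary but not sufficient for rigidity in
  3D, so the detected components are *candidates* that may merge distinct
  rigid components (the double-banana being the canonical failure).

After each accepted edge the game checks whether the edge completed a
spanned (tight) vertex set: pebbles are gathered so the endpoints hold
exactly l, and if no further free pebble is reachable, the new component is
every vertex with no directed path to a free pebble elsewhere.  Components
found later absorb earlier ones they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ValidationError


def _as_nx(g) -> nx.Graph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.Graph) else g


@dataclass
class PebbleResult:
    accepted: list
    rejected: list
    components: list  # list[frozenset], maximal detected spanned sets
    state: "PebbleGame"


class PebbleGame:
    """State of a (k, l) pebble game over a fixed vertex set."""

    def __init__(self, vertices, k: int, l: int):
        if not (0 <= l <= 2 * k):
            raise ValidationError(f"(k, l) = ({k}, {l}) outside supported range")
        self.k, self.l = k, l
        self.bar_joint_3d = l == 2 * k
        self.peb: dict = {v: k for v in vertices}
        self.out: dict = {v: [] for v in vertices}  # directed multigraph
        self.accepted: list = []
        self.rejected: list = []
        self.components: list[frozenset] = []

    # -- pebble moves --------------------------------------------------------

    def _find_pebble(self, roots, hold):
        """Path from a root to a vertex with a free pebble, pebbles on `hold` excluded."""
        seen = set(roots)
        parent = {}
        stack = list(roots)
        while stack:
            x = stack.pop()
            if x not in hold and self.peb[x] > 0:
                path = [x]
                while path[-1] in parent:
                    path.append(parent[path[-1]])
                return path[::-1]  # root ... x
            for y in self.out[x]:
                if y not in seen:
                    seen.add(y)
                    parent[y] = x
                    stack.append(y)
        return None

    def _gather_one(self, target, hold) -> bool:
        """Move one free pebble onto `target`, reversing the path used."""
        path = self._find_pebble([target], set(hold) | {target})
        if path is None:
            return False
        self.peb[path[-1]] -= 1
        for a, b in zip(path, path[1:]):
            self.out[a].remove(b)
            self.out[b].append(a)
        self.peb[target] += 1
        return True

    def _gather(self, u, v, quota_u, quota_v) -> bool:
        while self.peb[u] < quota_u:
            if not self._gather_one(u, hold={v}):
                return False
        while self.peb[v] < quota_v:
            if not self._gather_one(v, hold={u}):
                return False
        return True

    def _gather_total(self, u, v, total) -> bool:
        """Gather pebbles on {u, v} until they hold `total` together (any split)."""
        while self.peb[u] + self.peb[v] < total:
            if self.peb[u] < self.k and self._gather_one(u, hold={v}):
                continue
            if self.peb[v] < self.k and self._gather_one(v, hold={u}):
                continue
            return False
        return True

    def _reach(self, roots) -> set:
        seen = set(roots)
        stack = list(roots)
        while stack:
            x = stack.pop()
            for y in self.out[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    def _trapped(self, exclude) -> set:
        """Vertices with no directed path to a free pebble outside `exclude`.

        A trapped vertex w certifies that Reach(w) is a closed set whose only
        free pebbles sit on `exclude` vertices -- the tight-subgraph witness
        of the sparsity counts.
        """
        rin: dict = {w: [] for w in self.peb}
        for a, outs in self.out.items():
            for b in outs:
                rin[b].append(a)
        targets = [w for w in self.peb if w not in exclude and self.peb[w] > 0]
        can_escape = set(targets)
        stack = list(targets)
        while stack:
            x = stack.pop()
            for y in rin[x]:
                if y not in can_escape:
                    can_escape.add(y)
                    stack.append(y)
        return {w for w in self.peb if w not in can_escape}

    def _undirected_region(self, roots) -> set:
        """Connected region of the accepted graph around `roots`."""
        rin: dict = {w: set() for w in self.peb}
        for a, outs in self.out.items():
            for b in outs:
                rin[a].add(b)
                rin[b].add(a)
        seen = set(roots)
        stack = list(roots)
        while stack:
            x = stack.pop()
            for y in rin[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    # -- edge insertion ------------------------------------------------------

    def insert(self, u, v) -> bool:
        """Try to insert edge (u, v); returns True if accepted (independent)."""
        if u == v:
            raise ValidationError("self-loops are not distance constraints")
        if self.bar_joint_3d:
            ok = self._independent_bar_joint_3d(u, v)
        else:
            ok = self._gather_total(u, v, self.l + 1)
        if not ok:
            self.rejected.append((u, v))
            if self.bar_joint_3d and self.peb[u] == self.k and self.peb[v] == self.k:
                # the redundant edge may expose the spanned set containing it
                trapped = self._trapped(exclude={u, v})
                if u in trapped and v in trapped:
                    self._register(frozenset(trapped))
                self._scan_hosts(u, v)
            return False
        # place the edge, consuming one pebble from u
        if self.peb[u] == 0:  # pragma: no cover - gather guarantees a pebble
            u, v = v, u
        self.peb[u] -= 1
        self.out[u].append(v)
        self.accepted.append((u, v))
        if self.bar_joint_3d:
            self._detect_bar_joint_3d(u, v)
        else:
            self._detect_sum_rule(u, v)
        return True

    def _independent_bar_joint_3d(self, u, v) -> bool:
        """3n - 6 count test: k pebbles on each endpoint and no trapped witness.

        With 2k pebbles held on u and v, a vertex w whose every pebble path
        ends on u or v certifies a closed subset spanning 3n' - 6 edges that
        contains u and v: the new edge would overfill it.  A bare pair traps
        nothing and is accepted (the count applies to subsets of >= 3).
        """
        if not self._gather(u, v, self.k, self.k):
            return False
        return not (self._trapped(exclude={u, v}) - {u, v})

    # -- component detection ---------------------------------------------------

    def _register(self, comp: frozenset) -> None:
        if len(comp) < 2:
            return
        self.components = [c for c in self.components if not c <= comp]
        self.components.append(comp)

    def _detect_sum_rule(self, u, v) -> None:
        # standard l < 2k detection: a completed tight set holds exactly its
        # l trivial-motion pebbles, all on the endpoints of the closing edge
        if self.peb[u] + self.peb[v] != self.l:
            return
        if self._find_pebble([u, v], hold={u, v}) is not None:
            return
        comp = frozenset(self._trapped(exclude={u, v}))
        if u in comp and v in comp:
            self._register(comp)

    def _detect_bar_joint_3d(self, u, v) -> None:
        # After placement the endpoints hold 2k - 1 = 5 pebbles; a completed
        # tight set holds exactly 6 (its trivial motions), so its sixth
        # resource is either a single free pebble on a host z inside the set
        # or one directed edge leaving the set.
        self._scan_hosts(u, v)

    def _scan_hosts(self, u, v) -> None:
        # Hosts (candidate carriers of a spanned set's spare pebble) are
        # tried directly; the leaving-edge configuration is converted into a
        # host by pulling one pebble onto a candidate interior vertex, which
        # reverses the leaving edge.
        region = self._undirected_region([u, v])
        found: list[frozenset] = []

        def try_host(z) -> bool:
            trapped = self._trapped(exclude={u, v, z})
            if u in trapped and v in trapped and z in trapped:
                comp = frozenset(trapped)
                self._register(comp)
                found.append(comp)
                return True
            return False

        for z in sorted((w for w in region if w not in (u, v) and self.peb[w] == 1),
                        key=str):
            try_host(z)
        for w in sorted((w for w in region if w not in (u, v) and self.peb[w] == 0),
                        key=str):
            if any(w in c for c in found):
                continue
            if self._gather_one(w, hold={u, v}):
                try_host(w)

    def run(self, edges) -> PebbleResult:
        for u, v in edges:
            self.insert(u, v)
        return PebbleResult(
            list(self.accepted), list(self.rejected), list(self.components), self
        )

    # -- debugging -----------------------------------------------------------

    def is_sparse(self, min_size: int = 3) -> bool:
        """Verify the (k, l) count on every vertex subset by enumeration (slow)."""
        import itertools

        vs = sorted(self.peb)
        for size in range(min_size, len(vs) + 1):
            for sub in itertools.combinations(vs, size):
                s = set(sub)
                count = sum(1 for a, b in self.accepted if a in s and b in s)
                if count > self.k * size - self.l:
                    return False
        return True

    def dump(self) -> str:
        """TSV of directed edges and pebble counts, for debugging."""
        lines = ["vertex\tpebbles\tout_edges"]
        for v in sorted(self.peb):
            outs = ",".join(str(w) for w in sorted(self.out[v], key=str))
            lines.append(f"{v}\t{self.peb[v]}\t{outs}")
        return "\n".join(lines)


def pebble_components(g, k: int = 3, l: int = 6) -> list[frozenset]:
    """Run the (k, l) pebble game on a simple graph; return detected components.

    With (3, 6) the result is the 3D bar-joint heuristic: candidate
    components that may strictly contain true rigid components.  With
    (2, 3) the result is exact for 2D rigidity.
    """
    nxg = _as_nx(g)
    edges = sorted(tuple(sorted((u, v))) for u, v in nxg.edges)
    game = PebbleGame(sorted(nxg.nodes), k, l)
    return [c for c in game.run(edges).components if len(c) >= 3]


def run_pebble_game(g, k: int = 3, l: int = 6, edge_order=None) -> PebbleResult:
    """As :func:`pebble_components` but returning accepted/rejected edges too."""
    nxg = _as_nx(g)
    if edge_order is None:
        edge_order = sorted(tuple(sorted((u, v))) for u, v in nxg.edges)
    game = PebbleGame(sorted(nxg.nodes), k, l)
    return game.run(edge_order)


# ---------------------------------------------------------------------------
# Body-bar-and-hinge frameworks
# ---------------------------------------------------------------------------

HINGE_MULTIPLICITY = 5  # a hinge removes 5 of the 6 relative freedoms


@dataclass
class BodyBarHingeMultigraph:
    """Rigid bodies connected by hinges (5 parallel edges) and bars (1 edge)."""

    bodies: list
    hinges: list = field(default_factory=list)  # pairs of bodies
    bars: list = field(default_factory=list)  # pairs of bodies

    def validate(self) -> None:
        for a, b in list(self.hinges) + list(self.bars):
            if a == b:
                raise ValidationError("self-connections between a body and itself")
            if a not in self.bodies or b not in self.bodies:
                raise ValidationError(f"connection on unknown body {a!r} or {b!r}")


def body_bar_components(f: BodyBarHingeMultigraph) -> list[frozenset]:
    """Maximal mutually rigid body sets of a body-bar-and-hinge framework.

    Runs the exact (6, 6) pebble game on the multigraph in which each hinge
    contributes 5 parallel edges and each bar one edge.  Bodies in no
    multi-body rigid set are returned as singletons.
    """
    f.validate()
    game = PebbleGame(list(f.bodies), 6, 6)
    edges = []
    for a, b in sorted(f.hinges, key=lambda p: sorted(map(str, p))):
        edges.extend([(a, b)] * HINGE_MULTIPLICITY)
    for a, b in sorted(f.bars, key=lambda p: sorted(map(str, p))):
        edges.append((a, b))
    result = game.run(edges)
    comps = list(result.components)
    covered = set().union(*comps) if comps else set()
    comps.extend(frozenset([b]) for b in f.bodies if b not in covered)
    return sorted(comps, key=lambda c: (-len(c), sorted(map(str, c))))
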