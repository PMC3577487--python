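# Methods

## Model

A chromosome conformation graph `G = (V, E)` has one vertex per genomic
fragment center (chromosome label + base-pair coordinate) and one edge per
observed spatial interaction, weighted by interaction frequency.  Edges are
read as fixed-distance constraints between fragment centers.  Rigidity
analysis asks which vertex subsets are *generically rigid* in R³ — no
continuous motion except isometries preserves all constraint lengths — and
deliberately ignores the numerical frequencies: whether a structure is
sufficiently constrained should not depend on an (unsettled) mapping from
frequency to distance.  The only place frequencies enter is preprocessing
(filters) and the metric-consistency check.

"Rigid" here means *well-constrained by the data*, not physically frozen: a
rigid region has finitely many embeddings consistent with the constraints,
a floppy one has a continuum.

## Rank testing

The rigidity matrix at embedding `p` has one row per edge with `p_u − p_v`
in `u`'s three columns and the negation in `v`'s.  Generic rank is a graph
invariant; a random embedding is generic with probability 1 (Lebesgue) and,
over a finite field, with probability `≥ 1 − poly(n)/p` (Schwartz–Zippel).

* **Exact backend (default):** coordinates drawn uniformly from
  `GF(p)`, `p = 2³¹ − 1`, rank by vectorized Gaussian elimination mod `p`
  (int64 products stay below 2⁶²).  No tolerance is involved; a degenerate
  draw can only *lower* the rank, never raise it, so the verdict takes the
  maximum over `trials = 3` embeddings (one generic draw suffices; retrials
  guard against astronomically unlikely degeneracy).
* **Float backend:** singular values with relative threshold
  `1e-8 × σ_max`.  Kept for speed comparisons; the test suite asserts both
  backends agree on all fixtures.

Rank bound: `min(n(n−1)/2, 3n − 6)`, which handles `n < 3` (a single edge
has rank 1).  Graphs on 1–2 vertices are trivially rigid by convention and
never reported as components; reported components have ≥ 3 vertices.
Degrees of freedom: `dof = (3n − 6) − rank`; `rigid ⇔ dof = 0`.

The same machinery runs in dimension 2 (bound `2n − 3`) where it serves as
an independent oracle for the exact (2, 3) pebble game.

## Pebble games

One state machine implements all three games used.  Every vertex starts
with `k` pebbles; placing an accepted edge consumes one pebble of an
endpoint and directs the edge away from it; free pebbles move by reversing
directed paths.  The invariant `pebbles(v) + outdeg(v) = k` gives, for any
vertex set `S`, `Σ pebbles(S) + edges leaving S = k|S| − edges inside S`,
which is the accounting behind both acceptance and component detection.

* **Sum rule (`l < 2k`; used at (2, 3) and (6, 6)):** accept an edge iff
  `l + 1` pebbles can be gathered on its endpoints.  After placement a
  completed tight set holds exactly `l` pebbles, all on the endpoints; the
  component is every vertex with no directed path to a free pebble
  elsewhere.  Exact for 2D rigidity and, by Tay's theorem, for
  body-bar-and-hinge multigraphs at (6, 6) with hinges as 5 parallel edges
  and bars as single edges.
* **3D bar-joint variant (`(k, l) = (3, 6)`, `l = 2k`):** `l + 1 = 7`
  pebbles cannot sit on two vertices, so the rule is: gather `k` pebbles on
  each endpoint; the edge is independent iff no *trapped* vertex exists — a
  vertex whose every pebble path ends on the held endpoints, which would
  certify a subset already spanning `3n′ − 6` edges.  Bare pairs are
  exempt (the count applies to subsets of ≥ 3 vertices).  This enforces the
  Maxwell count, which in 3D is necessary but not sufficient: the
  double-banana passes every count yet is flexible, so detected components
  are candidates that can over-merge.

  Component detection at (3, 6): after placing an edge the endpoints hold
  `2k − 1 = 5` pebbles while a completed tight set owns 6 resources, so the
  sixth is either a free pebble on one interior host vertex or a single
  directed edge leaving the set.  Host candidates are tested directly
  (trapped-set computation with the host's pebble discounted); the
  leaving-edge configuration is converted into a host by pulling one pebble
  onto an interior vertex, which reverses the leaving edge.  Detection also
  runs when an edge is *rejected* with all `2k` pebbles gathered, because a
  tight set whose closing edge is redundant elsewhere never sees that edge
  accepted; sets detected on the reject path may merge overlapping tight
  sets — acceptable, since every candidate is rank-verified downstream.
  Newly detected components absorb previously detected subsets.

Edge insertion order is sorted (deterministic) by default; the
minimally-rigid sampler shuffles it per sample.  At (3, 6) the accepted set
is order-independent exactly when the graph is count-tight (e.g. the
double-banana always accepts all 18 edges); in general the accepted basis
and, on pathological graphs, even its size may vary with order — which is
precisely what makes permutation sampling informative.

## Body-bar-and-hinge reduction

1. Peel vertices of degree ≤ 2 to a fixed point (3-core).  Such vertices
   cannot join a rigid component of ≥ 4 vertices, but they *can* close
   size-3 components: every triangle containing a peeled vertex is recorded
   and reported as a size-3 rigid component.  (This generalizes the
   isolated-triangle case and is what lets the reduction return both
   triangles of the two-triangles-sharing-a-vertex graph, which has no
   body-bar-and-hinge representation.)
2. Grow seeds: pick a triangle not contained in any current body and add,
   repeatedly, a vertex with ≥ 3 edges into the grown set (vertex
   3-addition preserves rigidity).  `max` mode picks the triangle/vertex of
   largest degree (edges to already-used vertices not counted); `any` picks
   the first in deterministic order.  `any` is the default: both modes
   return identical components on all fixtures and random graphs tested,
   and `any` avoids the O(n³) max-triangle search.
3. Merge bodies sharing ≥ 3 vertices (generic 3-gluing); the fixed point is
   order-independent because overlaps only grow under union.
4. Select `R2`: greedily admit bodies (largest first) whose overlap with
   every admitted body is exactly 0 or 2; the rest are passed through
   unreduced (a 1-vertex overlap is representable neither as hinge nor
   bar).  Each 2-overlap pair whose shared vertex pair is unused becomes a
   hinge (processed by decreasing combined body size); then edges of `G`
   between body-exclusive vertices become bars, scanned in lexicographic
   order, skipping any endpoint already carrying a hinge or bar.  When
   three or more bodies share one vertex pair, only the first pair is
   hinged; the remaining bodies simply stay unconnected and are returned as
   their own (rigid) components.
5. Run the (6, 6) game on the body multigraph and map locked body sets back
   to vertex unions; append pass-through bodies and rescued triangles; drop
   sets contained in another.

Every returned set is rigid (3-addition, 3-gluing, and the hinge/bar rules
all preserve rigidity), but maximality is not guaranteed.

## Hybrid finder

Per connected component: run the (3, 6) game; rank-test each candidate of
size ≥ 3; report rigid candidates (`pebble_verified`), decompose floppy
ones with the reduction (`bbh_reduced`).  Finally, triangles not inside any
reported component are reported as size-3 components
(`isolated_triangle`): a triangle is always rigid, and on graphs of ≤ 9
vertices every rigid component contains one (`3s − 6 > s²/4` for
`s ≤ 9`), which is what makes small-graph oracle comparisons two-way.
Components never span connected components.  Sizes 1–2 are suppressed
unless requested.

In per-fragment assignment tables (sweeps, CLI output) a vertex lying in
several overlapping components is assigned to the largest; the component
list itself keeps the overlap.

## Filters

* **Frequency:** remove exactly `floor(x/100 · m)` measured edges, ordered
  by ascending frequency with lexicographic vertex-pair tie-breaking
  (reproducibility under ties).  Monotone: a stricter cutoff keeps a subset.
* **Genomic distance:** remove intra-chromosomal measured edges spanning
  `< x` kb; inter-chromosomal edges are always kept.
* **Metric:** map frequencies to distances (default `1/f`; also `f^−a` and
  a strictly decreasing user table with linear interpolation) and keep an
  edge iff its length equals the weighted shortest-path distance between
  its endpoints in the full weighted graph, within relative tolerance 1e-9
  (shortest-path sums are floating).  Single pass over the full graph; the
  suite asserts the result is idempotent and metrically closed.

Filters act on measured edges only; backbone edges added by augmentation
carry no frequency (they are pure adjacency constraints) and are never
filtered, weighted, or used in the metric check.  Filters compose in the
order given; the CLI applies frequency → genomic distance → metric.

## Augmentation

`augment` adds all fragments of a fragment table (observed or not) and one
backbone edge per consecutive intra-chromosomal pair; inter-chromosomal
backbone edges are never created.  A backbone edge coinciding with a
measured edge keeps the measured frequency and gains the flag.  Unobserved
fragments enter with degree ≤ 2, so they never change components of size
≥ 4; augmentation never removes anything, so the largest component can only
grow (edge addition is rigidity-monotone).

## Synthetic data

* `double_banana()`: two K5-minus-an-edge bodies sharing the missing edge's
  endpoints — 8 vertices, 18 edges, rank 17.
* `isostatic_graph(n, seed)`: triangle plus repeated random vertex
  3-addition: exactly `3n − 6` edges, rigid, edge-minimal.
* `configuration_rewire(g, seed)`: degree-preserving double-edge swaps
  (simple graph preserved; target `10·m` successful swaps, capped at
  `100×` that many attempts so swap-free graphs such as a triangle return
  unchanged).  Swaps rather than stub-matching because self-loops and
  parallel edges have no meaning as distance constraints.
* `toy_conformation_graph(spec)`: fragments evenly spaced (default 2
  chromosomes × 60 fragments, 10 kb apart); intra-chromosomal pairs within
  the 50 kb short-range span get an edge with probability 0.9, all other
  pairs with 0.01; frequencies are geometric positive integers whose mean
  decays exponentially from 30 (adjacent) toward 3 (long-range/
  inter-chromosomal).  The defaults emulate the short-range contact
  enrichment and heavy-tailed counts of real conformation data at a size
  where exact rank tests stay fast; they deliberately do *not* model
  polymer physics, domain structure, normalization biases, or realistic
  genome sizes — so passing tests demonstrate algorithmic correctness and
  qualitative filter behavior, not quantitative claims about any organism.

## Problem sizes, determinism, degenerate inputs

The acceptance script uses ~380 graphs: random graphs with 4–9 vertices
across densities (where the brute-force oracle — exhaustive rank tests over
vertex subsets, guarded at 12 vertices — is exact), isostatic growths to 25
vertices, and 80-fragment toy genomes; it completes in well under a minute.
All randomness (embeddings, random graphs, toy genomes, shuffles) derives
from a single seed; identical inputs and seeds give identical outputs.
Empty graphs yield empty component lists; an empty vertex set is rejected
by the rank test; parallel measurements are summed on load, zero-frequency
and self-pairs dropped; negative frequencies and malformed rows are errors
(with line numbers).

## Known limitations

* Reported components may be non-maximal on graphs near the `3n − 6`
  threshold whose structure has no body-bar-and-hinge representation;
  soundness (no floppy set reported) is the guarantee, maximality is not.
* The (3, 6) game is a heuristic: candidates can merge true components
  (implied hinges) and its accepted basis can depend on insertion order.
* Exact rank testing costs `O(m · (3n)²)` per candidate; it is the
  bottleneck on large graphs (the float backend is available when that
  matters).
* Generic rigidity assumes fragment centers in general position; exactly
  collinear/coplanar real geometries are outside the model, as are
  frequency normalization and statistical significance filtering, which are
  upstream of this package.
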