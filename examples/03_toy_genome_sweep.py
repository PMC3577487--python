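"""Rigidity sweeps: which interactions hold the structure together?

Profiles the rigid components of a toy conformation graph while removing
(a) increasing fractions of low-frequency interactions and (b) all
interactions below increasing genomic spans.  The giant rigid component
survives moderate frequency filtering but collapses as soon as the
short-range interactions -- the backbone of constraints -- are removed.
"""

import rigidscan as rs

spec = rs.ToyGenomeSpec(n_chromosomes=2, fragments_per_chromosome=40, seed=11)
g = rs.toy_conformation_graph(spec)
print(f"toy genome: {g.n} fragments, {g.m} interactions\n")

print("frequency sweep (largest rigid component):")
grid = [rs.FilterSpec("frequency_percent", x) for x in (0, 25, 50, 75, 95)]
for point in rs.sweep(g, grid):
    pct = point.filters[0].x
    print(f"  drop {pct:>4.0f}% lowest-frequency -> largest {point.largest:>3}, "
          f"total in components {point.total:>3}")

print("\ngenomic-distance sweep:")
grid = [rs.FilterSpec("genomic_distance_kb", x) for x in (0, 20, 50)]
for point in rs.sweep(g, grid):
    kb = point.filters[0].x
    print(f"  remove spans < {kb:>3.0f} kb -> largest {point.largest:>3}, "
          f"total {point.total:>3}")
print("\nthe collapse at the short-range span shows rigidity rests on"
      "\nshort-range contacts, not on the rarer long-range ones")
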