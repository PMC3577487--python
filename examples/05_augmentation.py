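"""Augmented conformation graphs: modelling the linear chromatin fiber.

An augmented graph adds every genomic fragment (observed or not) and a
backbone edge between consecutive fragments.  Backbone edges can close
triangles and enlarge rigid components, but unobserved fragments enter with
degree <= 2 and can never join a rigid component of 4 or more vertices.
"""

import rigidscan as rs

A, B, C, D, E = (rs.FragmentID("chr1", 100 * (i + 1)) for i in range(5))
g = rs.ConformationGraph.from_edges(
    [(A, B, 1.0), (A, C, 2.0), (A, D, 3.0), (B, D, 4.0)]
)
print(f"measured graph: n={g.n}, m={g.m}; components:",
      [sorted(map(str, c.vertices)) for c in rs.find_rigid_components(g)])

frags = rs.FragmentTable({"chr1": [100, 200, 300, 400, 500]})
aug = rs.augment(g, frags)
print(f"augmented:      n={aug.n}, m={aug.m} "
      f"(backbone edges flagged, E added although unobserved)")
comps = rs.find_rigid_components(aug)
print("components after augmentation:",
      [sorted(map(str, c.vertices)) for c in comps])
print("  the backbone edges B-C and C-D close a rigid triangle with the")
print("  measured B-D interaction; unobserved E (degree 1) stays outside")
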