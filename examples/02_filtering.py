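"""The three preprocessing filters on a toy conformation graph.

Conformation-capture interaction lists are noisy: most interactions are
rare or short-range.  Before asking which regions are rigid, one filters by
interaction frequency, by genomic span, or by metric consistency under a
frequency-to-distance mapping.
"""

import rigidscan as rs

spec = rs.ToyGenomeSpec(seed=4)
g = rs.toy_conformation_graph(spec)
print(f"toy genome: {g.n} fragments, {g.m} interactions")

f1 = rs.filter_frequency(g, 50)
print(f"frequency filter (drop lowest 50%): {f1.m} interactions left")

f2 = rs.filter_genomic_distance(g, 30)
print(f"genomic-distance filter (< 30 kb removed): {f2.m} interactions left")

res = rs.filter_metric(g, rs.DistanceMapping(form="inverse"))
print(f"metric filter (distance = 1/frequency): kept {res.graph.m}, "
      f"removed {len(res.removed)} metric-violating interactions")
print("  a removed edge claims its endpoints are farther apart than some")
print("  path through higher-frequency interactions allows")
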