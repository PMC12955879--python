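"""Cross-species divergence between planted homologous regions.

Two synthetic species share a tract dictionary; five homologous region
pairs are planted with divergence delta from 0 (identical tract profiles)
to 1 (independent). The measured region-wise symmetric KL divergence
should grow with delta.
"""

import numpy as np

import afblueprint as af

deltas = [0.0, 0.25, 0.5, 0.75, 1.0]
spec = dict(n_vertices=200, n_regions=10, n_tracts=6, count_depth=1e4)
plan = af.HomologyPlan(tuple((i, i, d) for i, d in enumerate(deltas)))
pair = af.generate_species_pair(af.SpeciesSpec("human", **spec),
                                af.SpeciesSpec("macaque", **spec), plan, seed=8)

bp_h = af.normalize_rows(af.build_blueprint(pair.a.c1, pair.a.c2))
bp_m = af.normalize_rows(af.build_blueprint(pair.b.c1, pair.b.c2))
vd = af.vertexwise_divergence(bp_h, bp_m)
rd = af.regionwise_divergence(vd, pair.a.parcellation, pair.b.parcellation)

print("planted delta -> measured region-wise symmetric KL (bits):")
for i, d in enumerate(deltas):
    print(f"  delta={d:4.2f}  KL={rd.values[i, i]:.4f}")

min_map = af.min_divergence_map(rd, "rows")
print("min divergence per human region:", np.round(min_map, 3))
# KL is in bits (base-2 logs). delta=0 pairs measure ~0 (identical
# profiles up to count noise); larger delta yields larger divergence.
# The min-divergence map shows, per region, its closest match in the
# other species.
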