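"""Joint spectral embedding of two species' regions.

Region-profile divergences are assembled into one symmetric joint matrix,
converted to similarity by exp(-d), and embedded into 2-D with Laplacian
eigenmaps. Homologous pairs with low planted divergence land close
together; distance in the plane quantifies cross-species correspondence.
"""

import pandas as pd

import afblueprint as af

deltas = [0.0, 0.25, 0.5, 0.75, 1.0]
spec = dict(n_vertices=200, n_regions=10, n_tracts=6, count_depth=1e4)
plan = af.HomologyPlan(tuple((i, i, d) for i, d in enumerate(deltas)))
pair = af.generate_species_pair(af.SpeciesSpec("human", **spec),
                                af.SpeciesSpec("macaque", **spec), plan, seed=8)

bp_h = af.normalize_rows(af.build_blueprint(pair.a.c1, pair.a.c2))
bp_m = af.normalize_rows(af.build_blueprint(pair.b.c1, pair.b.c2))
rp_h = af.region_profile(bp_h, pair.a.parcellation)
rp_m = af.region_profile(bp_m, pair.b.parcellation)

joint = af.assemble_joint(af.profile_divergence(rp_h, rp_h),
                          af.profile_divergence(rp_m, rp_m),
                          af.profile_divergence(rp_h, rp_m),
                          "human", "macaque")
emb = af.spectral_embed(af.to_similarity(joint))

pairs = pd.DataFrame([
    {"unit_a": f"human:{pair.a.parcellation.region_ids[i]}",
     "unit_b": f"macaque:{pair.b.parcellation.region_ids[i]}",
     "lobe": f"delta={deltas[i]}"}
    for i in range(5)])
dists = af.pair_distances(emb, pairs)
print(dists[["lobe", "distance"]].round(4).to_string(index=False))
# Euclidean distance between homologs in the embedding plane tracks the
# planted divergence: conserved pairs (delta=0) nearly coincide. A single
# simulated draw is noisy at high delta; averaged over replicates the
# distance is strictly increasing in delta.
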