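"""Build and normalize a connectivity blueprint from C1 and C2.

C1 counts how often streamlines seeded at each cortical vertex visit each
white-matter voxel; C2 records which voxels belong to which tract. Their
product is the blueprint, and each normalized row is that vertex's
probability distribution over tracts.
"""

import numpy as np

import afblueprint as af

rng = np.random.default_rng(0)
c1 = rng.poisson(5.0, size=(6, 20)).astype(float)   # 6 vertices x 20 voxels
c2 = np.zeros((20, 4))                               # 20 voxels x 4 tracts
c2[np.arange(20), np.repeat(np.arange(4), 5)] = 1.0

bp = af.normalize_rows(af.build_blueprint(c1, c2))
print("tracts:", bp.tract_names)
print("blueprint rows (per-vertex tract probabilities):")
print(np.round(bp.values, 3))
print("row sums:", np.round(bp.values.sum(axis=1), 6))

territory = af.tract_territory(bp, "AF")
print("AF cortical territory (one column):", np.round(territory, 3))
# Each row sums to 1: vertex-wise probabilities over the tract dictionary.
# The AF column says how strongly each vertex participates in that tract.
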