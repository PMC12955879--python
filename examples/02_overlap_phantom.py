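"""Score spatial overlap between two tract volumes with a known answer.

Generates a paired curved-tube phantom targeting a Szymkiewicz-Simpson
coefficient of 0.5, then scores it globally, per coronal slice, and by
anterior/middle/posterior segments — the same workflow used to compare a
microscopy-derived axon mask against a tractography density map.
"""

import numpy as np

import afblueprint as af

vp = af.generate_volume_pair(af.PhantomSpec(
    grid_shape=(32, 32, 64), target_overlap=0.5, seed=3))
print(f"target overlap 0.5, achieved {vp.achieved_overlap:.3f}")
print(f"global coefficient: {af.overlap_coefficient(vp.mask_a, vp.mask_b):.3f}")

per_slice = af.slicewise_overlap(vp.mask_a, vp.mask_b, axis=2)
scheme = af.SegmentScheme(segments={
    "anterior": (1, 21), "middle": (22, 42), "posterior": (43, 64)})
print(af.segment_stats(per_slice, scheme).round(3).to_string(index=False))
# The coefficient is |A∩B| / min(|A|,|B|): 1 means the smaller tube is
# contained in the larger, 0 means they are disjoint. Segment rows give the
# per-slice mean, SD and a normal-approximation 95% CI.
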