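"""Run the full synthetic pipeline and inspect the report tables.

Simulates two species with a lobe-graded homology plan (frontal pairs
diverge most, insular least), builds group-averaged blueprints from four
subjects each, computes vertex- and region-wise divergence, selects
AF-connected regions, embeds both species jointly, and writes every table
plus a manifest to an output directory.
"""

import afblueprint as af

cfg = af.RunConfig(seed=1)
result = af.run_full_pipeline(cfg, out_dir="scratch/example_run")

print("planted per-lobe divergence:", cfg.lobe_delta)
print("\nhomolog-pair KL by lobe (bits):")
print(result.tables["homolog_kl"].groupby("lobe")["kl"].mean().round(3))
print("\nsame-lobe divergence-block summary:")
print(result.tables["lobe_kl"].round(3).to_string(index=False))
print("\nAF-connected regions:",
      len(result.selection_a), "human,", len(result.selection_b), "macaque")
# The homolog-pair KL means rank lobes exactly by the planted divergence
# (frontal > temporal > parietal > insular), which is the ground-truth
# check that the full chain — simulation, blueprints, divergence,
# aggregation — preserves the planted cross-species structure.
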