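# afblueprint

Cross-species comparison of white-matter connectivity blueprints, built
around the arcuate fasciculus (AF) — the dorsal language tract whose
human-specific expansion is a central question in comparative
neuroanatomy. The package provides a tested, reusable implementation of
the full analysis chain used to compare tract connectivity between two
species (e.g. human and macaque), together with a synthetic-connectome
generator with planted ground truth so every stage can be validated
without imaging data.

## What it computes

**Connectivity blueprints.** From a whole-brain visitation matrix
C1 (cortical vertices × white-matter voxels) and a tract-map matrix
C2 (voxels × tracts), the blueprint is the product B = C1·C2
(cortex × tracts). After row normalization, row *i* is vertex *i*'s
probability distribution over a tract dictionary shared across species
(AF, SLF1–3, MdLF, IFOF, ILF, UF, ATR, OR, CST, PTR); column *t* is tract
*t*'s cortical territory. Per-subject blueprints are normalized, averaged
across subjects, and re-normalized.

**Divergence.** Dissimilarity between two units' tract profiles p, q is
the symmetric Kullback–Leibler divergence in bits:

    D(p, q) = Σ_k p_k log2(p_k/q_k) + Σ_k q_k log2(q_k/p_k)

computed for every cross-species vertex pair, then aggregated to region
pairs by the median over each parcellation block. Minimum-divergence maps,
AF-connected region selection (region-mean AF probability > 0.10), and
per-lobe summaries with Mann–Whitney U / FDR statistics follow.

**Joint embedding.** Within- and cross-species region divergence blocks
are assembled into one symmetric joint matrix [[W_A, W_AB], [W_ABᵀ, W_B]],
transformed to similarity by exp(−d), and embedded in 2-D with Laplacian
eigenmaps; Euclidean distance in the plane quantifies cross-species
correspondence of homologous regions.

**Overlap validation.** Agreement between a microscopy-derived axon mask
and a tractography density map (binarized at 0.5) is scored with the
Szymkiewicz–Simpson coefficient |A∩B| / min(|A|,|B|), globally, per
coronal slice, and by anterior/middle/posterior segments.

**Connectome maps.** Streamline endpoint pairs are counted per region
pair, weak connections (< 5 streamlines) removed, matrices normalized to
unit total weight, and averaged across subjects.

## Worked example

Five homologous region pairs are planted with divergence δ from 0
(identical latent tract profiles) to 1 (independent), and the measured
region-wise symmetric KL divergence recovers the gradient
(`examples/03_cross_species_divergence.py`):

```
planted delta -> measured region-wise symmetric KL (bits):
  delta=0.00  KL=0.0008
  delta=0.25  KL=0.2081
  delta=0.50  KL=0.6680
  delta=0.75  KL=1.7117
  delta=1.00  KL=2.0393
```

Identical profiles measure ≈ 0 bits (pure count noise); fully independent
profiles here measure ≈ 2 bits. The full pipeline
(`examples/05_full_pipeline.py`, seed 1) plants a per-lobe divergence
gradient (frontal 0.8 > temporal 0.45 > parietal 0.3 > insular 0.15) and
the homolog-pair KL means recover the same ordering:

```
homolog-pair KL by lobe (bits):
frontal     1.832
temporal    0.444
parietal    0.283
insular     0.122
```

The other examples cover blueprint construction (`01`), overlap phantoms
(`02`), and the joint embedding (`04`). A thin CLI wraps the
shell-runnable pieces: `afblueprint run`, `afblueprint simulate-phantom`,
`afblueprint overlap-score`.

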