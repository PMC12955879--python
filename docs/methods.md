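# Methods

## Connectivity blueprints

A blueprint is the product B = C1·C2 of a whole-brain visitation matrix
C1 (cortical vertices × white-matter voxels, nonnegative streamline
visitation counts) and a tract-map matrix C2 (voxels × tracts). Rows are
normalized to unit sum so each vertex carries a probability distribution
over a tract dictionary fixed in a canonical order and shared across the
species being compared; the default dictionary is the twelve major
bundles AF, SLF1–3, MdLF, IFOF, ILF, UF, ATR, OR, CST, PTR. Vertices with
zero support (e.g. medial-wall seeds that launch no streamlines) are
flagged invalid and excluded from all probability computations rather
than filled uniformly — filling would fabricate connectivity and bias
divergences downward.

Group averaging is normalize-per-subject → elementwise mean →
re-normalize rows. The order is a genuine design choice (averaging raw
blueprints first would weight subjects by their total streamline counts);
normalizing first keeps subjects equally weighted, and `group_average`
exposes `renormalize` for the alternative convention. A vertex is valid
in the group only if valid in every subject.

Region profiles are arithmetic means of valid vertex rows within each
parcellation region; vertex indexing is 0-based throughout.

## Symmetric KL divergence

Dissimilarity between tract profiles p and q is
D(p,q) = Σ p_k log2(p_k/q_k) + Σ q_k log2(q_k/p_k), in bits. Zero
components would make D infinite, so each profile is regularized by
adding ε = 1e-8 to every component and renormalizing before the sum; on
strictly positive profiles this perturbs values by O(ε) (the test suite
checks < 1e-6 under halving ε). The vertex-wise matrix is computed
vectorized as Σ (p−q)(log2 p − log2 q) over all pairs and clipped at 0 to
remove −1e-16-scale float residue.

Region-wise aggregation takes the **median over the full block** of
vertex-pair entries (|R_A|·|R_B| values per region pair), ignoring
invalid pairs. The median is robust to the long right tail that sparse
profiles produce.

AF-connected region selection uses the region-mean AF probability with a
strict > 0.10 threshold, applied independently per species; the joint
matrix is then restricted to species A's selected rows and species B's
selected columns.

Lobe summaries pool all entries whose row- and column-regions carry the
same lobe label; lobe pairs are compared with two-sided Mann–Whitney U on
block entries, Benjamini–Hochberg corrected across pairs.

## Joint similarity and spectral embedding

The joint matrix is the symmetric block form [[W_A, W_AB], [W_ABᵀ, W_B]];
the lower-left block is the transpose of the upper-right, which is exact
because the divergence is argument-symmetric. For the embedding path the
blocks are computed at the **region-profile level** (symmetric KL between
region-mean profiles) rather than by vertex-pair medians: this makes the
within-species blocks exactly symmetric with an exactly zero diagonal, as
a similarity graph requires, whereas a median-aggregated within-species
matrix has a small nonzero diagonal (the median vertex-pair divergence
inside a region) and is not a valid self-similarity. The median-based
aggregation remains the implementation for the divergence maps and lobe
statistics, where it is the intended estimator.

Similarity is exp(−d), entries in (0,1], diagonal 1. The embedding is
Laplacian eigenmaps with a fully fixed convention so results are
bit-reproducible: symmetric-normalized Laplacian
L = I − D^(−1/2) W D^(−1/2) with self-similarities kept as given; dense
`eigh`; drop the constant eigenvector; take the two smallest nontrivial
eigenpairs; map eigenvectors back through D^(−1/2); normalize each
component to unit Euclidean norm; weight component c by its random-walk
eigenvalue 1 − λ_c (diffusion-map scaling — a direction that barely
diffuses, λ ≈ 1, contributes proportionally nothing, which is what makes
two perfect similarity blocks collapse to two points); fix signs so each
component's largest-magnitude coordinate is positive. A disconnected
similarity graph is rejected with the component sizes (it cannot occur
with exp(−d) > 0 but can with user-supplied similarities). Absolute
embedding coordinates depend on this scaling convention, so cross-species
distances are interpreted relatively (ranks, ratios, planted-gradient
recovery), never as absolute calibrated values.

## Overlap validation

The Szymkiewicz–Simpson coefficient |A∩B| / min(|A|,|B|) is used; it is
1 exactly when the smaller set is contained in the larger and 0 for
disjoint sets. Density maps are binarized with voxel ≥ threshold → 1
(default 0.5): the rule zeroes voxels *below* threshold, so boundary
voxels are kept. Per-slice evaluation treats slices where both masks are
empty as recorded gaps (NaN) and slices where exactly one mask is empty
as 0 — missing tract coverage is penalized, not skipped. Segment
statistics report mean, sample SD (ddof = 1), and the normal-approximation
CI mean ± 1.96·SD/√n per named slice range; the default scheme is the
anterior/middle/posterior convention (inclusive 1-based coronal slices
42–65 / 66–89 / 90–113), overridable in `SegmentScheme`.

## Connectome pipeline

Fixed order: count unordered endpoint pairs → remove connections with
fewer than 5 streamlines (strict <, exactly 5 survives) → scale so the
upper triangle sums to 1 → average normalized matrices across subjects.
Sum-to-one over unique connections was chosen as the normalization
because a row-stochastic alternative breaks symmetry; it is the only
stage choice not forced by the counting semantics.

## Statistics

All tests are two-sided. Mann–Whitney U uses the exact null when the
combined sample is ≤ 20 without ties, otherwise the normal approximation
with tie correction; Wilcoxon signed-rank drops zero differences and
rejects degenerate all-zero inputs. FDR is Benjamini–Hochberg step-up.
Summaries report mean, sample SD, and mean ± 1.96·SD/√n; a single
observation gets SD 0 and a degenerate interval. Small-sample p-values
are verified in the tests against full enumeration (all group
assignments; all 2^n sign patterns) implemented independently of the
library used at runtime.

## Synthetic data generator

The generator emulates the matrix-level statistical structure the
analysis consumes, not imaging:

- **Latent region profiles** are drawn from a symmetric Dirichlet with
  concentration 0.5 (default), giving sparse, few-dominant-tract profiles
  like normalized blueprint rows. Homologous pairs mix a shared draw with
  an independent one: p_B = (1−δ)·p_A + δ·q. δ = 0 plants identical
  profiles, δ = 1 independent ones, and expected measured divergence is
  monotone in δ.
- **Counts**: each vertex's voxel visitations are Poisson around
  count_depth × profile / voxels_per_tract. count_depth defaults to 1000,
  matching the convention of seeding 1000 streamlines per vertex; the
  count noise model itself is a modeling choice, since streamline
  visitation overdispersion in real tractography is not characterized
  here.
- **C2** is a crisp tract-territory indicator with a 1% additive
  background so blueprints are strictly positive; the background mixes
  ~1% uniform mass into measured profiles (the tests account for this),
  and keeps ε-regularization from dominating planted-recovery checks.
- **Parcellations** are contiguous near-equal vertex blocks with regions
  assigned round-robin to four lobes (frontal, temporal, parietal,
  insular).
- **Volume phantoms** are curved-tube masks; the partner tube is the same
  centerline displaced perpendicular to its course, with the displacement
  found by bisection until the achieved coefficient is within 0.05
  (typically 0.01) of target. Unreachable targets (grid too small to
  separate the tubes) raise with the feasible range.
- One integer seed drives everything through `numpy` `SeedSequence`
  spawning — one substream for latent profiles, one per species for
  counts — so identical specs + seed give bitwise-identical output.

What passing synthetic tests do **not** show: real blueprints have
spatially autocorrelated profiles, hemispheric asymmetries, registration
error, and non-Poisson count dispersion; recovery of planted δ here
validates the estimator chain, not robustness to those features.

## Pipeline defaults and problem sizes

The default `RunConfig` simulates a 30-region/240-vertex and a
24-region/192-vertex species over the 12-tract dictionary, 4 subjects
each, pairing region i with region i and grading planted δ by lobe
(frontal 0.8, temporal 0.45, parietal 0.3, insular 0.15) so the expected
lobe ordering of divergence is known. Tests and the acceptance script use
30 regions × 8 vertices, 6 tracts, count_depth 1e4, and 20 replicates for
recovery checks — sizes at which the Monte-Carlo means are stable while a
full run completes in seconds on one CPU. All tabular output is written
with a fixed float format and no timestamps, so reruns with the same seed
are byte-identical (hashes recorded in the manifest).

## Known limitations

- Absolute embedding distances are convention-dependent (see above).
- The ε = 1e-8 regularization biases divergences involving exactly-zero
  components slightly downward relative to the +∞ of the unregularized
  definition; rankings are unaffected.
- The overlap phantom controls the global coefficient, not per-slice
  values; slicewise behaviour is validated on constructed cases instead.
- `segment_stats` CIs use the normal approximation; for n < ~20 slices a
  t or bootstrap interval would be wider (switchable via the `z`
  argument of `summarize` only in scale, not in family).
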