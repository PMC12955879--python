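"""Synthetic paired-species connectomes and volume phantoms with known truth.

Real connectivity blueprints come from probabilistic tractography; here the
matrix-level structure the analysis consumes is generated directly, so every
downstream stage can be tested against planted ground truth:

* Each region of each species carries a latent tract-probability profile on
  a shared tract dictionary, drawn from a symmetric Dirichlet.
* Homologous region pairs mix a shared profile with an independent one at a
  controllable divergence weight delta: delta 0 plants identical profiles,
  delta 1 independent ones, and the expected measured divergence is
  monotone in delta.
* Per-vertex white-matter visitation counts (the C1 matrix) are Poisson
  around count_depth x profile — the count nature of streamline visitation —
  and the tract-map matrix C2 is a crisp tract-territory indicator with a
  small additive background so blueprints stay strictly positive.
* Paired curved-tube volume masks are constructed to hit a requested
  Szymkiewicz-Simpson overlap coefficient, for testing the overlap module.

One integer seed governs everything; per-species and per-purpose substreams
are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .blueprint import DEFAULT_TRACTS, TractMapMatrix, WholeBrainMatrix
from .overlap import overlap_coefficient
from .parcellation import DEFAULT_LOBES, Parcellation, contiguous_parcellation

C2_BACKGROUND = 0.01  # additive background as a fraction of the indicator peak


@dataclass(frozen=True)
class SpeciesSpec:
    """Size and noise parameters of one synthetic species.

    count_depth is the expected total visitation count per vertex (the
    analogue of streamlines seeded per vertex); profile_concentration is the
    symmetric-Dirichlet concentration of the latent tract profiles — values
    below 1 give sparse, few-dominant-tract profiles like normalized
    blueprint rows.
    """

    name: str
    n_vertices: int
    n_regions: int
    n_tracts: int
    profile_concentration: float = 0.5
    count_depth: float = 1000.0
    voxels_per_tract: int = 40
    lobes: tuple[str, ...] = DEFAULT_LOBES

    def __post_init__(self) -> None:
        if not (self.n_vertices >= self.n_regions >= len(self.lobes) >= 1):
            raise ValueError(
                "need n_vertices >= n_regions >= number of lobes >= 1, got "
                f"{self.n_vertices}/{self.n_regions}/{len(self.lobes)}"
            )
        if self.n_tracts < 2:
            raise ValueError("need at least 2 tracts")
        if self.profile_concentration <= 0 or self.count_depth <= 0:
            raise ValueError("profile_concentration and count_depth must be positive")

    @property
    def n_voxels(self) -> int:
        return self.n_tracts * self.voxels_per_tract

    @property
    def tract_names(self) -> tuple[str, ...]:
        return tuple(
            DEFAULT_TRACTS[k] if k < len(DEFAULT_TRACTS) else f"T{k}"
            for k in range(self.n_tracts)
        )


@dataclass(frozen=True)
class HomologyPlan:
    """Planted homologous-region pairs: (region_A, region_B, delta).

    delta in [0, 1] is the divergence of the pair's latent profiles:
    p_B = (1 - delta) * p_A + delta * q with q an independent draw.
    """

    pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        seen_a, seen_b = set(), set()
        for ra, rb, delta in self.pairs:
            if ra in seen_a:
                raise ValueError(f"region {ra} of species A named twice in plan")
            if rb in seen_b:
                raise ValueError(f"region {rb} of species B named twice in plan")
            if not (0.0 <= delta <= 1.0):
                raise ValueError(f"delta must lie in [0, 1], got {delta}")
            seen_a.add(ra)
            seen_b.add(rb)

    def validate_against(self, spec_a: SpeciesSpec, spec_b: SpeciesSpec) -> None:
        for ra, rb, _ in self.pairs:
            if not (0 <= ra < spec_a.n_regions):
                raise ValueError(f"plan names region {ra} outside species A")
            if not (0 <= rb < spec_b.n_regions):
                raise ValueError(f"plan names region {rb} outside species B")


@dataclass(frozen=True)
class SpeciesData:
    """One species' generated matrices plus its ground truth."""

    spec: SpeciesSpec
    c1: WholeBrainMatrix
    c2: TractMapMatrix
    parcellation: Parcellation
    latent_profiles: np.ndarray  # n_regions x n_tracts, rows sum to 1


@dataclass(frozen=True)
class SpeciesPair:
    a: SpeciesData
    b: SpeciesData
    plan: HomologyPlan


def _dirichlet(rng: np.random.Generator, concentration: float, k: int) -> np.ndarray:
    return rng.dirichlet(np.full(k, concentration))


def sample_latent_profiles(
    spec_a: SpeciesSpec,
    spec_b: SpeciesSpec,
    plan: HomologyPlan,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent region profiles for both species under the homology plan."""
    if spec_a.n_tracts != spec_b.n_tracts:
        raise ValueError("tract dictionaries must be identical across species")
    plan.validate_against(spec_a, spec_b)
    k = spec_a.n_tracts
    prof_a = np.stack([
        _dirichlet(rng, spec_a.profile_concentration, k)
        for _ in range(spec_a.n_regions)
    ])
    prof_b = np.stack([
        _dirichlet(rng, spec_b.profile_concentration, k)
        for _ in range(spec_b.n_regions)
    ])
    for ra, rb, delta in plan.pairs:
        q = _dirichlet(rng, spec_b.profile_concentration, k)
        prof_b[rb] = (1.0 - delta) * prof_a[ra] + delta * q
    return prof_a, prof_b


def tract_map(spec: SpeciesSpec) -> TractMapMatrix:
    """Crisp tract-territory indicator C2 with a small additive background."""
    tract_of_voxel = np.repeat(np.arange(spec.n_tracts), spec.voxels_per_tract)
    c2 = np.full((spec.n_voxels, spec.n_tracts), C2_BACKGROUND)
    c2[np.arange(spec.n_voxels), tract_of_voxel] = 1.0
    return TractMapMatrix(c2, spec.tract_names)


def sample_counts(
    spec: SpeciesSpec,
    profiles: np.ndarray,
    parcellation: Parcellation,
    rng: np.random.Generator,
) -> WholeBrainMatrix:
    """Poisson visitation counts C1 for one subject.

    Vertex v in region r visits voxel w of tract t with expected count
    count_depth * p_r[t] / voxels_per_tract, so the expected row profile of
    C1 @ C2 equals the region's latent profile up to the C2 background.
    """
    tract_of_voxel = np.repeat(np.arange(spec.n_tracts), spec.voxels_per_tract)
    rates = (
        spec.count_depth
        * profiles[parcellation.vertex_region][:, tract_of_voxel]
        / spec.voxels_per_tract
    )
    return WholeBrainMatrix(rng.poisson(rates).astype(float))


def generate_species_pair(
    spec_a: SpeciesSpec, spec_b: SpeciesSpec, plan: HomologyPlan, seed: int
) -> SpeciesPair:
    """Generate one subject's (C1, C2, parcellation) for each of two species.

    Sub-streams are spawned deterministically from ``seed``: one for the
    latent profiles (shared structure), one per species for counts.
    """
    ss = np.random.SeedSequence(seed)
    rng_latent, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))
    prof_a, prof_b = sample_latent_profiles(spec_a, spec_b, plan, rng_latent)
    out = []
    for spec, prof, rng in ((spec_a, prof_a, rng_a), (spec_b, prof_b, rng_b)):
        parc = contiguous_parcellation(
            spec.n_vertices, spec.n_regions, spec.lobes, prefix=f"{spec.name}_"
        )
        c1 = sample_counts(spec, prof, parc, rng)
        out.append(SpeciesData(spec, c1, tract_map(spec), parc, prof))
    return SpeciesPair(out[0], out[1], plan)


# --------------------------------------------------------------------------
# Volume phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Paired curved-tube masks targeting a given overlap coefficient."""

    grid_shape: tuple[int, int, int] = (32, 32, 64)
    target_overlap: float = 0.5
    tube_radius: float = 3.0
    seed: int = 0
    n_centerline_points: int = 200

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError(f"grid must be at least (16,16,16), got {self.grid_shape}")
        if not (0.0 <= self.target_overlap <= 1.0):
            raise ValueError("target_overlap must lie in [0, 1]")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")


@dataclass(frozen=True)
class VolumePair:
    mask_a: np.ndarray
    mask_b: np.ndarray
    achieved_overlap: float
    spec: PhantomSpec = field(repr=False, default=None)


def _centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Curved arc through the grid, bowing in x, running along z."""
    nx, ny, nz = spec.grid_shape
    r = spec.tube_radius
    t = np.linspace(0.0, 1.0, spec.n_centerline_points)
    amp = (0.5 + 0.5 * rng.random()) * max(1.0, 0.25 * nx - r)
    phase = rng.random() * np.pi
    x = nx / 2 + amp * np.sin(np.pi * t + phase) - amp * np.sin(phase)
    x = np.clip(x, r + 1, nx - r - 2)
    y = np.full_like(t, r + 1.0)
    z = (r + 1.0) + t * (nz - 2 * r - 3.0)
    return np.column_stack([x, y, z])


def _tube_mask(centerline: np.ndarray, grid_shape, radius: float,
               voxel_centers: np.ndarray) -> np.ndarray:
    tree = cKDTree(centerline)
    dist, _ = tree.query(voxel_centers, k=1)
    return (dist <= radius).reshape(grid_shape)


def generate_volume_pair(spec: PhantomSpec) -> VolumePair:
    """Two curved-tube masks whose overlap coefficient hits the target.

    Mask B is mask A's tube displaced perpendicular to its course; the
    displacement is found by bisection so the achieved coefficient lands
    within 0.05 of ``target_overlap``. Raises with the feasible range when
    the grid is too small to separate the tubes far enough.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    center = _centerline(spec, rng)
    grids = np.meshgrid(*(np.arange(s) for s in spec.grid_shape), indexing="ij")
    voxel_centers = np.column_stack([g.ravel() for g in grids]).astype(float)
    mask_a = _tube_mask(center, spec.grid_shape, spec.tube_radius, voxel_centers)

    def mask_at(offset: float) -> np.ndarray:
        shifted = center + np.array([0.0, offset, 0.0])
        return _tube_mask(shifted, spec.grid_shape, spec.tube_radius, voxel_centers)

    if spec.target_overlap >= 1.0:
        return VolumePair(mask_a, mask_a.copy(), 1.0, spec)

    max_offset = ny - 2 * (spec.tube_radius + 1.0) - 1.0
    mask_far = mask_at(max_offset)
    ov_far = overlap_coefficient(mask_a, mask_far)
    if spec.target_overlap < ov_far - 0.05:
        raise ValueError(
            f"target overlap {spec.target_overlap} unreachable on grid "
            f"{spec.grid_shape} with tube radius {spec.tube_radius}; "
            f"feasible range is [{ov_far:.3f}, 1.0]"
        )
    lo, hi = 0.0, max_offset  # overlap(lo)=1, overlap(hi)=ov_far
    best_mask, best_ov = mask_far, ov_far
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = mask_at(mid)
        ov = overlap_coefficient(mask_a, m)
        if abs(ov - spec.target_overlap) < abs(best_ov - spec.target_overlap):
            best_mask, best_ov = m, ov
        if abs(ov - spec.target_overlap) <= 0.01:
            break
        if ov > spec.target_overlap:
            lo = mid
        else:
            hi = mid
    if abs(best_ov - spec.target_overlap) > 0.05:
        raise ValueError(
            f"could not reach overlap {spec.target_overlap} "
            f"(best achieved {best_ov:.3f}) on grid {spec.grid_shape}"
        )
    return VolumePair(mask_a, best_mask, best_ov, spec)
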