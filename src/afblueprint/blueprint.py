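"""Connectivity blueprints: build, normalize, aggregate, average.

A connectivity blueprint is a cortex x tracts matrix obtained as the product
of a whole-brain visitation matrix C1 (cortical vertices x white-matter
voxels) and a tract-map matrix C2 (voxels x tracts). After row
normalization, row v is the probability distribution describing how vertex v
connects to a fixed dictionary of white-matter tracts; column t is the
cortical territory of tract t. The tract dictionary is shared across the
species being compared, which is what makes the blueprints a common space
for cross-species analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parcellation import Parcellation

#: Canonical tract dictionary: dorsal language pathway (AF, SLF1-3), ventral
#: language pathway (MdLF, IFOF, ILF, UF), and other major bundles.
DEFAULT_TRACTS = (
    "AF", "SLF1", "SLF2", "SLF3", "MdLF", "IFOF",
    "ILF", "UF", "ATR", "OR", "CST", "PTR",
)

ROW_SUM_TOL = 1e-9


def _check_nonnegative(values: np.ndarray, what: str) -> None:
    if np.any(values < 0):
        raise ValueError(f"{what} contains negative entries")


@dataclass(frozen=True)
class WholeBrainMatrix:
    """C1: vertices x white-matter voxels, nonnegative visitation counts."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("whole-brain matrix must be 2-D")
        _check_nonnegative(v, "whole-brain matrix")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TractMapMatrix:
    """C2: white-matter voxels x tracts, nonnegative tract occupancy."""

    values: np.ndarray
    tract_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("tract-map matrix must be 2-D")
        if v.shape[1] != len(self.tract_names):
            raise ValueError(
                f"tract-map has {v.shape[1]} columns but "
                f"{len(self.tract_names)} tract names"
            )
        _check_nonnegative(v, "tract-map matrix")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Blueprint:
    """Vertices x tracts matrix; rows are tract profiles once normalized.

    ``valid`` flags rows with nonzero support; zero rows (e.g. medial-wall
    vertices that launch no streamlines) stay zero and are excluded from all
    downstream probability computations rather than being filled in.
    """

    values: np.ndarray
    tract_names: tuple[str, ...]
    normalized: bool = False
    valid: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.tract_names):
            raise ValueError("blueprint shape inconsistent with tract names")
        _check_nonnegative(v, "blueprint")
        valid = self.valid
        if valid is None:
            valid = v.sum(axis=1) > 0
        valid = np.asarray(valid, dtype=bool)
        if self.normalized:
            sums = v[valid].sum(axis=1)
            if sums.size and np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
                raise ValueError("normalized blueprint has valid rows not summing to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", valid)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracts(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegionProfiles:
    """Region x tracts matrix of mean tract probabilities per region."""

    values: np.ndarray
    tract_names: tuple[str, ...]
    region_ids: tuple[str, ...]
    valid: np.ndarray  # region has at least one valid vertex


def build_blueprint(c1, c2) -> Blueprint:
    """Multiply C1 (vertices x voxels) by C2 (voxels x tracts).

    Accepts the wrapper types or plain arrays; plain-array C2 uses the
    canonical tract dictionary truncated/padded to its width.
    """
    if not isinstance(c1, WholeBrainMatrix):
        c1 = WholeBrainMatrix(np.asarray(c1))
    if not isinstance(c2, TractMapMatrix):
        arr = np.asarray(c2)
        names = tuple(
            DEFAULT_TRACTS[k] if k < len(DEFAULT_TRACTS) else f"T{k}"
            for k in range(arr.shape[1])
        )
        c2 = TractMapMatrix(arr, names)
    if c1.values.shape[1] != c2.values.shape[0]:
        raise ValueError(
            f"inner dimensions do not match: C1 is {c1.values.shape}, "
            f"C2 is {c2.values.shape}"
        )
    return Blueprint(c1.values @ c2.values, c2.tract_names, normalized=False)


def normalize_rows(bp: Blueprint) -> Blueprint:
    """Divide every row with positive sum by its sum; flag zero rows invalid."""
    _check_nonnegative(bp.values, "blueprint")
    sums = bp.values.sum(axis=1)
    valid = sums > 0
    out = np.zeros_like(bp.values)
    out[valid] = bp.values[valid] / sums[valid, None]
    return Blueprint(out, bp.tract_names, normalized=True, valid=valid,
                     provenance=bp.provenance)


def group_average(bps: list[Blueprint], renormalize: bool = True) -> Blueprint:
    """Elementwise mean of per-subject blueprints.

    All inputs must share shape, tract order and normalization state.
    Normalize-then-average keeps each subject equally weighted; with
    ``renormalize`` (default) rows are re-normalized afterwards so the group
    blueprint is again row-stochastic on its valid rows. A vertex is valid in
    the group only if it is valid in every subject.
    """
    if not bps:
        raise ValueError("need at least one blueprint")
    first = bps[0]
    states = {bp.normalized for bp in bps}
    if len(states) > 1:
        raise ValueError("cannot average a mix of normalized and unnormalized blueprints")
    for bp in bps[1:]:
        if bp.values.shape != first.values.shape:
            raise ValueError("blueprint shapes differ across subjects")
        if bp.tract_names != first.tract_names:
            raise ValueError("tract order differs across subjects")
    mean = np.mean([bp.values for bp in bps], axis=0)
    valid = np.logical_and.reduce([bp.valid for bp in bps])
    mean[~valid] = 0.0
    out = Blueprint(mean, first.tract_names, normalized=False, valid=valid,
                    provenance=f"group(n={len(bps)})")
    if first.normalized:
        out = normalize_rows(out) if renormalize else replace(out, normalized=True)
        out = replace(out, valid=valid, provenance=f"group(n={len(bps)})")
    return out


def tract_territory(bp: Blueprint, tract: str) -> np.ndarray:
    """One blueprint column: the per-vertex cortical territory of a tract."""
    if tract not in bp.tract_names:
        raise KeyError(
            f"unknown tract {tract!r}; available tracts: {list(bp.tract_names)}"
        )
    return bp.values[:, bp.tract_names.index(tract)].copy()


def region_profile(bp: Blueprint, parc: Parcellation) -> RegionProfiles:
    """Average tract-probability distribution per parcellation region.

    Only valid (nonzero-support) vertices contribute; a region whose
    vertices are all invalid is flagged and its profile left at zero.
    """
    if not bp.normalized:
        raise ValueError("region profiles are defined on normalized blueprints")
    if parc.n_vertices != bp.n_vertices:
        raise ValueError(
            f"parcellation covers {parc.n_vertices} vertices but blueprint "
            f"has {bp.n_vertices}"
        )
    values = np.zeros((parc.n_regions, bp.n_tracts))
    valid = np.zeros(parc.n_regions, dtype=bool)
    for r in range(parc.n_regions):
        members = parc.vertices_of(r)
        ok = members[bp.valid[members]]
        if ok.size:
            values[r] = bp.values[ok].mean(axis=0)
            valid[r] = True
    return RegionProfiles(values, bp.tract_names, parc.region_ids, valid)
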