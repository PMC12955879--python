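"""Spatial overlap between microscopy- and tractography-derived tract masks.

Agreement between a microscopy-derived axon mask and a tractography-derived
track-density map is scored with the Szymkiewicz-Simpson overlap
coefficient

    overlap(A, B) = |A ∩ B| / min(|A|, |B|)

which is 1 exactly when the smaller voxel set is contained in the larger
and 0 when the sets are disjoint. Density maps (normalized streamline
visitation in [0, 1]) are first binarized at a threshold, 0.5 by default;
voxels below the threshold are zeroed, so a voxel exactly at threshold is
kept. Coefficients can be evaluated per coronal slice and aggregated into
named anterior/middle/posterior segment statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import summarize

#: Default coronal segment scheme (inclusive 1-based slice numbers).
DEFAULT_SEGMENTS = {
    "anterior": (42, 65),
    "middle": (66, 89),
    "posterior": (90, 113),
}

DENSITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class SegmentScheme:
    """Named, non-overlapping slice ranges along one axis.

    Ranges are inclusive and 1-based by default (the convention slice
    numbers are reported in); set ``one_based=False`` for 0-based ranges.
    """

    axis: int = 2
    segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )
    one_based: bool = True

    def __post_init__(self) -> None:
        spans = sorted(self.segments.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ValueError(f"segment ranges overlap: {(a0, a1)} and {(b0, b1)}")
        for name, (lo, hi) in self.segments.items():
            if lo > hi:
                raise ValueError(f"segment {name!r} has empty range {(lo, hi)}")

    def indices(self, name: str, n_slices: int) -> np.ndarray:
        lo, hi = self.segments[name]
        if self.one_based:
            lo, hi = lo - 1, hi - 1
        if lo < 0 or hi >= n_slices:
            raise ValueError(
                f"segment {name!r} range {self.segments[name]} exceeds grid "
                f"with {n_slices} slices"
            )
        return np.arange(lo, hi + 1)


def binarize_density(values: np.ndarray, threshold: float = DENSITY_THRESHOLD) -> np.ndarray:
    """Threshold a normalized track-density volume into a binary mask.

    Voxels >= threshold become 1 (values exactly at threshold are kept,
    since only voxels *below* threshold are zeroed).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("density volume contains non-finite values")
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("density values must lie in [0, 1]")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return (values >= threshold).astype(np.uint8)


def overlap_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Szymkiewicz-Simpson coefficient |A∩B| / min(|A|,|B|) of two masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("overlap undefined: both masks are empty")
    if min(na, nb) == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / min(na, nb))


def slicewise_overlap(a: np.ndarray, b: np.ndarray, axis: int = 2) -> np.ndarray:
    """Overlap coefficient evaluated independently on every slice along ``axis``.

    Slices where both masks are empty are NaN (a recorded gap); slices where
    exactly one mask is empty score 0 — absent tract coverage is penalized,
    not skipped.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    if not (0 <= axis < a.ndim):
        raise ValueError(f"axis {axis} invalid for {a.ndim}-D volume")
    n = a.shape[axis]
    out = np.full(n, np.nan)
    for k in range(n):
        sa = np.take(a, k, axis=axis)
        sb = np.take(b, k, axis=axis)
        na, nb = int(sa.sum()), int(sb.sum())
        if na == 0 and nb == 0:
            continue
        out[k] = 0.0 if min(na, nb) == 0 else np.logical_and(sa, sb).sum() / min(na, nb)
    return out


def segment_stats(per_slice: np.ndarray, scheme: SegmentScheme) -> pd.DataFrame:
    """Mean, sample SD, and normal-approximation 95% CI per named segment.

    NaN slices (gaps where both masks were empty) are excluded; a segment
    with no scored slices is flagged with n = 0 and NaN statistics.
    """
    per_slice = np.asarray(per_slice, dtype=float)
    rows = []
    for name in scheme.segments:
        vals = per_slice[scheme.indices(name, per_slice.size)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append({"segment": name, "mean": np.nan, "sd": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "n": 0})
            continue
        s = summarize(vals)
        rows.append({"segment": name, "mean": s.mean, "sd": s.sd,
                     "ci_low": s.ci_low, "ci_high": s.ci_high, "n": s.n})
    return pd.DataFrame(rows)
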