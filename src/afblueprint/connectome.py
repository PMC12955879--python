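"""Group-level tract-restricted connectome matrices from streamline endpoints.

For one subject and one tract, each streamline contributes an unordered
region pair (its two endpoint parcels). The group pipeline is fixed:
count inter-regional streamlines, remove weak (likely false-positive)
connections below a streamline threshold of 5, normalize each subject's
matrix so its unique connections sum to 1, and average the normalized
matrices across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STREAMLINE_THRESHOLD = 5


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric region x region connectivity matrix."""

    values: np.ndarray
    region_ids: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} inconsistent with {n} regions")
        if np.any(v < 0):
            raise ValueError("connectome entries must be nonnegative")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectome matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def upper_triangle_sum(self) -> float:
        iu = np.triu_indices(len(self.region_ids))
        return float(self.values[iu].sum())


def count_connectome(endpoints, region_ids: tuple[str, ...]) -> ConnectomeMatrix:
    """Count streamlines per unordered region pair.

    ``endpoints`` is an iterable of (region_a, region_b) label pairs, or a
    DataFrame with columns ``region_a``/``region_b``, one row per streamline.
    """
    if isinstance(endpoints, pd.DataFrame):
        endpoints = list(zip(endpoints["region_a"], endpoints["region_b"]))
    index = {name: i for i, name in enumerate(region_ids)}
    n = len(region_ids)
    values = np.zeros((n, n))
    for ra, rb in endpoints:
        if ra not in index or rb not in index:
            unknown = ra if ra not in index else rb
            raise KeyError(f"unknown region label {unknown!r} in endpoint list")
        i, j = index[ra], index[rb]
        values[i, j] += 1
        if i != j:
            values[j, i] += 1
    return ConnectomeMatrix(values, region_ids, normalized=False)


def threshold_connectome(
    cm: ConnectomeMatrix, min_streamlines: int = STREAMLINE_THRESHOLD
) -> ConnectomeMatrix:
    """Zero out connections with fewer than ``min_streamlines`` streamlines.

    The comparison is strict (<), so a connection with exactly
    ``min_streamlines`` streamlines survives.
    """
    if cm.normalized:
        raise ValueError("thresholding applies to count matrices, not normalized ones")
    values = np.where(cm.values < min_streamlines, 0.0, cm.values)
    return ConnectomeMatrix(values, cm.region_ids, normalized=False)


def normalize_connectome(cm: ConnectomeMatrix) -> ConnectomeMatrix:
    """Scale so the upper triangle (unique connections) sums to 1."""
    if cm.normalized:
        return cm
    total = cm.upper_triangle_sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return ConnectomeMatrix(cm.values / total, cm.region_ids, normalized=True)


def group_mean_connectome(cms: list[ConnectomeMatrix]) -> ConnectomeMatrix:
    """Elementwise mean of per-subject normalized matrices."""
    if not cms:
        raise ValueError("need at least one connectome")
    first = cms[0]
    for cm in cms:
        if cm.region_ids != first.region_ids:
            raise ValueError("parcellation differs across subjects")
        if not cm.normalized:
            raise ValueError("group mean is defined on normalized matrices")
    mean = np.mean([cm.values for cm in cms], axis=0)
    return ConnectomeMatrix(mean, first.region_ids, normalized=True)


def build_group_connectome(
    per_subject_endpoints: list,
    region_ids: tuple[str, ...],
    min_streamlines: int = STREAMLINE_THRESHOLD,
) -> ConnectomeMatrix:
    """Full pipeline: count -> threshold -> normalize per subject -> mean."""
    normalized = [
        normalize_connectome(
            threshold_connectome(count_connectome(ep, region_ids), min_streamlines)
        )
        for ep in per_subject_endpoints
    ]
    return group_mean_connectome(normalized)
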