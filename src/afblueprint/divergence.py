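"""Symmetric KL divergence between tract-probability profiles.

The dissimilarity between two units (vertices or regions) is the symmetric
Kullback-Leibler divergence, in base-2 logarithms, between their tract
distributions p and q:

    D(p, q) = sum_k p_k log2(p_k / q_k) + sum_k q_k log2(q_k / p_k)

Profiles are regularized before the sum — an epsilon is added to every
component and the profile renormalized — so that zero components (a tract a
vertex never reaches) keep the divergence finite. On strictly positive
profiles the regularization perturbs the value by O(epsilon).

Vertex-wise divergence between two species' group blueprints yields an
i x j matrix; region-wise divergence aggregates it by the median over all
vertex pairs in each region block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blueprint import Blueprint, RegionProfiles, region_profile
from .parcellation import Parcellation
from .stats import TestResult, fdr_adjust, mann_whitney_u

DEFAULT_EPSILON = 1e-8
AF_CONTRIBUTION_THRESHOLD = 0.10


def _regularize(p: np.ndarray, eps: float) -> np.ndarray:
    p = p + eps
    return p / p.sum(axis=-1, keepdims=True)


def symmetric_kl(p, q, eps: float = DEFAULT_EPSILON) -> float:
    """Symmetric KL divergence (base 2) between two probability profiles."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile lengths differ: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or v.sum() <= 0:
            raise ValueError(f"profile {name} is not a valid distribution")
    p = _regularize(p / p.sum(), eps)
    q = _regularize(q / q.sum(), eps)
    lp, lq = np.log2(p), np.log2(q)
    return float(np.sum((p - q) * (lp - lq)))


@dataclass(frozen=True)
class DivergenceMatrix:
    """Pairwise symmetric KL divergences between two sets of units.

    ``values[i, j]`` is the divergence between unit i of side A and unit j
    of side B; entries involving invalid units are NaN. ``level`` records
    whether units are vertices or regions.
    """

    values: np.ndarray
    level: str
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _profile_cross_divergence(P: np.ndarray, Q: np.ndarray, eps: float) -> np.ndarray:
    """All-pairs symmetric KL between rows of P and rows of Q (vectorized)."""
    P = _regularize(P, eps)
    Q = _regularize(Q, eps)
    lP, lQ = np.log2(P), np.log2(Q)
    # sum_k (p-q)(lp-lq) = [p.lp] + [q.lq] - p.lq' - lp.q'
    a = np.sum(P * lP, axis=1)[:, None]
    b = np.sum(Q * lQ, axis=1)[None, :]
    return a + b - P @ lQ.T - lP @ Q.T


def vertexwise_divergence(
    bp_a: Blueprint, bp_b: Blueprint, eps: float = DEFAULT_EPSILON
) -> DivergenceMatrix:
    """Symmetric KL between every vertex of A and every vertex of B.

    Both blueprints must be normalized and share the tract dictionary.
    Invalid vertices (zero support) produce NaN rows/columns.
    """
    if not (bp_a.normalized and bp_b.normalized):
        raise ValueError("vertex-wise divergence requires normalized blueprints")
    if bp_a.tract_names != bp_b.tract_names:
        raise ValueError(
            f"tract dictionaries differ: {bp_a.tract_names} vs {bp_b.tract_names}"
        )
    out = np.full((bp_a.n_vertices, bp_b.n_vertices), np.nan)
    ia, ib = np.flatnonzero(bp_a.valid), np.flatnonzero(bp_b.valid)
    if ia.size and ib.size:
        block = _profile_cross_divergence(bp_a.values[ia], bp_b.values[ib], eps)
        out[np.ix_(ia, ib)] = np.maximum(block, 0.0)  # clip float negatives ~ -1e-16
    return DivergenceMatrix(
        out, "vertex",
        tuple(f"A{v}" for v in range(bp_a.n_vertices)),
        tuple(f"B{v}" for v in range(bp_b.n_vertices)),
    )


def regionwise_divergence(
    vd: DivergenceMatrix, parc_a: Parcellation, parc_b: Parcellation
) -> DivergenceMatrix:
    """Median vertex-pair divergence per region pair.

    Entry (R_A, R_B) is the median over the |R_A| x |R_B| block of the
    vertex-wise matrix, ignoring invalid (NaN) pairs; a block with no valid
    pair stays NaN.
    """
    if vd.level != "vertex":
        raise ValueError("expected a vertex-level divergence matrix")
    if (parc_a.n_vertices, parc_b.n_vertices) != vd.shape:
        raise ValueError(
            f"parcellations cover {(parc_a.n_vertices, parc_b.n_vertices)} "
            f"vertices but matrix is {vd.shape}"
        )
    out = np.full((parc_a.n_regions, parc_b.n_regions), np.nan)
    for ra in range(parc_a.n_regions):
        rows = vd.values[parc_a.vertices_of(ra)]
        for rb in range(parc_b.n_regions):
            block = rows[:, parc_b.vertices_of(rb)]
            if np.any(~np.isnan(block)):
                out[ra, rb] = np.nanmedian(block)
    return DivergenceMatrix(out, "region", parc_a.region_ids, parc_b.region_ids)


def profile_divergence(
    rp_a: RegionProfiles, rp_b: RegionProfiles, eps: float = DEFAULT_EPSILON
) -> DivergenceMatrix:
    """Symmetric KL between region-mean profiles (region-level, zero diagonal
    when a set of profiles is compared against itself)."""
    if rp_a.tract_names != rp_b.tract_names:
        raise ValueError("tract dictionaries differ between region profiles")
    out = np.full((len(rp_a.region_ids), len(rp_b.region_ids)), np.nan)
    ia, ib = np.flatnonzero(rp_a.valid), np.flatnonzero(rp_b.valid)
    if ia.size and ib.size:
        block = _profile_cross_divergence(rp_a.values[ia], rp_b.values[ib], eps)
        out[np.ix_(ia, ib)] = np.maximum(block, 0.0)
    return DivergenceMatrix(out, "region", rp_a.region_ids, rp_b.region_ids)


def min_divergence_map(dm: DivergenceMatrix, direction: str = "rows") -> np.ndarray:
    """Per-unit minimum divergence to any unit of the other species.

    ``direction='rows'`` minimizes over columns for each row (a map over
    side-A units); ``'cols'`` the converse. Fully masked units give NaN.
    """
    if dm.values.size == 0:
        raise ValueError("empty divergence matrix")
    if direction not in ("rows", "cols"):
        raise ValueError("direction must be 'rows' or 'cols'")
    values = dm.values if direction == "rows" else dm.values.T
    out = np.full(values.shape[0], np.nan)
    any_valid = np.any(~np.isnan(values), axis=1)
    out[any_valid] = np.nanmin(values[any_valid], axis=1)
    return out


def select_af_connected(
    bp: Blueprint,
    parc: Parcellation,
    tract: str = "AF",
    threshold: float = AF_CONTRIBUTION_THRESHOLD,
) -> np.ndarray:
    """Region indices whose mean tract probability strictly exceeds ``threshold``.

    Selection operates on the region-mean profiles (region_profile); the
    default threshold of 0.10 picks out the regions the tract of interest
    actually reaches.
    """
    if tract not in bp.tract_names:
        raise KeyError(f"unknown tract {tract!r}; available: {list(bp.tract_names)}")
    rp = region_profile(bp, parc)
    contribution = rp.values[:, bp.tract_names.index(tract)]
    return np.flatnonzero(rp.valid & (contribution > threshold))


def lobe_summary(
    dm: DivergenceMatrix,
    lobes_a: tuple[str, ...],
    lobes_b: tuple[str, ...],
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean +/- SD of region-pair divergences within each same-lobe block.

    For each lobe, entries whose row region and column region both carry that
    lobe label are pooled (restricted to the selected regions when
    selections are given). Empty blocks are flagged with n = 0.
    """
    if len(lobes_a) != len(dm.row_ids) or len(lobes_b) != len(dm.col_ids):
        raise ValueError("lobe labels must cover the divergence matrix axes")
    sel_a = np.arange(len(dm.row_ids)) if selection_a is None else np.asarray(selection_a)
    sel_b = np.arange(len(dm.col_ids)) if selection_b is None else np.asarray(selection_b)
    rows = []
    for lobe in sorted(set(lobes_a) & set(lobes_b)):
        ra = [r for r in sel_a if lobes_a[r] == lobe]
        rb = [c for c in sel_b if lobes_b[c] == lobe]
        block = dm.values[np.ix_(ra, rb)].ravel() if ra and rb else np.array([])
        block = block[~np.isnan(block)]
        if block.size:
            rows.append({
                "lobe": lobe,
                "mean": float(block.mean()),
                "sd": float(block.std(ddof=1)) if block.size > 1 else 0.0,
                "n": int(block.size),
            })
        else:
            rows.append({"lobe": lobe, "mean": np.nan, "sd": np.nan, "n": 0})
    return pd.DataFrame(rows)


def _lobe_block(dm, lobes_a, lobes_b, sel_a, sel_b, lobe) -> np.ndarray:
    ra = [r for r in sel_a if lobes_a[r] == lobe]
    rb = [c for c in sel_b if lobes_b[c] == lobe]
    if not ra or not rb:
        return np.array([])
    block = dm.values[np.ix_(ra, rb)].ravel()
    return block[~np.isnan(block)]


def compare_lobes(
    dm: DivergenceMatrix,
    lobes_a: tuple[str, ...],
    lobes_b: tuple[str, ...],
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between same-lobe divergence
    blocks, Benjamini-Hochberg corrected across lobe pairs.

    Lobe pairs with fewer than ``min_n`` entries in either block are recorded
    but not tested.
    """
    sel_a = np.arange(len(dm.row_ids)) if selection_a is None else np.asarray(selection_a)
    sel_b = np.arange(len(dm.col_ids)) if selection_b is None else np.asarray(selection_b)
    lobes = sorted(set(lobes_a) & set(lobes_b))
    records, tested = [], []
    for i, l1 in enumerate(lobes):
        for l2 in lobes[i + 1:]:
            b1 = _lobe_block(dm, lobes_a, lobes_b, sel_a, sel_b, l1)
            b2 = _lobe_block(dm, lobes_a, lobes_b, sel_a, sel_b, l2)
            rec = {"lobe_1": l1, "lobe_2": l2, "n_1": b1.size, "n_2": b2.size,
                   "statistic": np.nan, "p_value": np.nan, "p_fdr": np.nan,
                   "tested": False}
            if b1.size >= min_n and b2.size >= min_n:
                res: TestResult = mann_whitney_u(b1, b2)
                rec.update(statistic=res.statistic, p_value=res.p_value, tested=True)
                tested.append(len(records))
            records.append(rec)
    df = pd.DataFrame(records)
    if tested:
        df.loc[tested, "p_fdr"] = fdr_adjust(df.loc[tested, "p_value"].to_numpy())
    return df
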