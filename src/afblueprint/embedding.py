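"""Joint similarity construction and spectral embedding of brain regions.

The within- and cross-species region-wise divergence matrices are
concatenated into one symmetric joint matrix

    W_joint = [[W_A,    W_AB],
               [W_AB^T, W_B ]]

over the union of both species' regions, converted to a similarity by
exp(-d), and embedded into 2-D with Laplacian eigenmaps so that regions with
similar tract profiles — within or across species — land near one another.
Cross-species correspondence is then read off as plain Euclidean distance in
the embedding plane.

The embedding convention is fixed for determinism: symmetric-normalized
graph Laplacian (self-similarities kept as given), the eigenvectors of the
two smallest nontrivial eigenvalues, rows scaled by D^{-1/2}, each
component normalized to unit Euclidean norm and weighted by its
random-walk eigenvalue 1 - lambda (diffusion-map scaling, so directions
that barely diffuse contribute proportionally little), and the sign chosen
so the largest-magnitude coordinate of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .divergence import DivergenceMatrix
from .stats import TestResult, mann_whitney_u

SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class JointDivergence:
    values: np.ndarray              # (A+B) x (A+B), symmetric, zero diagonal
    unit_ids: tuple[str, ...]       # species-tagged ids, A block then B block
    species: tuple[str, ...]        # species tag per unit
    n_a: int


@dataclass(frozen=True)
class SimilarityMatrix:
    values: np.ndarray              # exp(-divergence), entries in (0, 1]
    unit_ids: tuple[str, ...]
    species: tuple[str, ...]


@dataclass(frozen=True)
class Embedding:
    coords: np.ndarray              # units x 2
    eigenvalues: np.ndarray         # the two retained Laplacian eigenvalues
    unit_ids: tuple[str, ...]
    species: tuple[str, ...]

    def coords_of(self, unit_id: str) -> np.ndarray:
        return self.coords[self.unit_ids.index(unit_id)]


def assemble_joint(
    w_a: DivergenceMatrix,
    w_b: DivergenceMatrix,
    w_ab: DivergenceMatrix,
    species_a: str = "A",
    species_b: str = "B",
) -> JointDivergence:
    """Assemble the symmetric joint divergence matrix from its blocks.

    ``w_a`` and ``w_b`` are the within-species region divergences (square,
    symmetric); ``w_ab`` the cross-species block on A-regions x B-regions.
    The lower-left block is the transpose of ``w_ab`` — valid because the
    symmetric KL divergence does not depend on argument order.
    """
    A, B = w_a.values.shape[0], w_b.values.shape[0]
    for name, w in (("within-A", w_a), ("within-B", w_b)):
        if w.values.shape[0] != w.values.shape[1]:
            raise ValueError(f"{name} block is not square: {w.values.shape}")
        if np.nanmax(np.abs(w.values - w.values.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError(f"{name} block asymmetric beyond {SYMMETRY_TOL}")
    if w_ab.values.shape != (A, B):
        raise ValueError(
            f"cross block must be {A}x{B}, got {w_ab.values.shape}"
        )
    joint = np.block([[w_a.values, w_ab.values], [w_ab.values.T, w_b.values]])
    if np.any(np.isnan(joint)):
        raise ValueError("joint matrix contains masked (NaN) entries; "
                         "restrict to valid regions first")
    unit_ids = tuple(f"{species_a}:{r}" for r in w_a.row_ids) + tuple(
        f"{species_b}:{r}" for r in w_b.row_ids
    )
    species = (species_a,) * A + (species_b,) * B
    return JointDivergence(joint, unit_ids, species, A)


def to_similarity(jd: JointDivergence) -> SimilarityMatrix:
    """Elementwise exp(-d): divergence 0 maps to similarity 1."""
    if np.any(jd.values < 0):
        raise ValueError("negative divergences violate the KL contract")
    return SimilarityMatrix(np.exp(-jd.values), jd.unit_ids, jd.species)


def spectral_embed(sm: SimilarityMatrix, n_components: int = 2,
                   seed: int | None = None) -> Embedding:
    """Laplacian-eigenmap coordinates of the similarity graph.

    ``seed`` is accepted for interface uniformity; the algorithm is a dense
    symmetric eigendecomposition and fully deterministic.
    """
    W = np.asarray(sm.values, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.max(np.abs(W - W.T)) > 1e-8:
        raise ValueError("similarity matrix must be symmetric")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"similarity graph is disconnected: {n_comp} components "
            f"of sizes {sizes.tolist()}"
        )
    d = W.sum(axis=1)
    inv_sqrt_d = 1.0 / np.sqrt(d)
    L = np.eye(W.shape[0]) - inv_sqrt_d[:, None] * W * inv_sqrt_d[None, :]
    evals, evecs = np.linalg.eigh(L)
    # evals ascending; index 0 is the trivial (constant) eigenvector.
    coords = np.empty((W.shape[0], n_components))
    for c in range(n_components):
        v = inv_sqrt_d * evecs[:, c + 1]
        v = v / np.linalg.norm(v)
        v = v * (1.0 - evals[c + 1])  # diffusion weighting
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, c] = v
    return Embedding(coords, evals[1 : n_components + 1], sm.unit_ids, sm.species)


def pair_distances(emb: Embedding, pairs: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between homologous-region pairs in the embedding.

    ``pairs`` needs columns ``unit_a`` and ``unit_b`` (embedding unit ids);
    an optional ``lobe`` column is carried through for grouped summaries.
    Pairs with a missing unit are recorded with NaN distance and
    ``found = False`` rather than raised.
    """
    index = {u: i for i, u in enumerate(emb.unit_ids)}
    records = []
    for row in pairs.itertuples(index=False):
        rec = {"unit_a": row.unit_a, "unit_b": row.unit_b,
               "lobe": getattr(row, "lobe", ""), "distance": np.nan,
               "found": False}
        if row.unit_a in index and row.unit_b in index:
            delta = emb.coords[index[row.unit_a]] - emb.coords[index[row.unit_b]]
            rec.update(distance=float(np.linalg.norm(delta)), found=True)
        records.append(rec)
    return pd.DataFrame(records)


def lobe_distance_summary(distances: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of pair distances per lobe (found pairs only)."""
    ok = distances[distances["found"]]
    rows = []
    for lobe, grp in ok.groupby("lobe"):
        d = grp["distance"].to_numpy()
        rows.append({"lobe": lobe, "mean": float(d.mean()),
                     "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                     "n": int(d.size)})
    return pd.DataFrame(rows)


def intra_cluster_distances(
    emb: Embedding, labels: dict[str, str]
) -> dict[str, np.ndarray]:
    """All within-cluster pairwise Euclidean distances.

    ``labels`` maps unit id -> cluster name; unlabeled units are ignored.
    Singleton clusters yield an empty distance array (flagged by size 0).
    """
    clusters: dict[str, list[int]] = {}
    for i, u in enumerate(emb.unit_ids):
        if u in labels:
            clusters.setdefault(labels[u], []).append(i)
    out = {}
    for name, idx in clusters.items():
        pts = emb.coords[idx]
        dists = [
            float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
        ]
        out[name] = np.asarray(dists)
    return out


def compare_clusters(
    dists: dict[str, np.ndarray], cluster_1: str, cluster_2: str
) -> TestResult:
    """Two-sided Mann-Whitney U between two clusters' intra-cluster distances."""
    d1, d2 = dists[cluster_1], dists[cluster_2]
    if d1.size < 1 or d2.size < 1:
        raise ValueError(
            f"need non-singleton clusters; sizes: {cluster_1}={d1.size}, "
            f"{cluster_2}={d2.size}"
        )
    return mann_whitney_u(d1, d2)
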