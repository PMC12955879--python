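"""Cortical parcellations: vertex -> region -> lobe lookup tables.

A parcellation assigns every cortical vertex to exactly one named region
(e.g. a Brainnetome or D99 atlas parcel) and, optionally, every region to a
lobe. Regions are indexed 0..n_regions-1 in a fixed order; ``vertex_region``
stores the region index of each vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_LOBES = ("frontal", "temporal", "parietal", "insular")


@dataclass(frozen=True)
class Parcellation:
    """Assignment of vertices to regions, and regions to lobes.

    Parameters
    ----------
    vertex_region
        Integer array of shape (n_vertices,); entry v is the region index of
        vertex v. Indices are 0-based and must cover 0..n_regions-1 with no
        empty region.
    region_ids
        Region names in index order.
    region_lobe
        Lobe label per region, same order as ``region_ids`` (optional).
    """

    vertex_region: np.ndarray
    region_ids: tuple[str, ...]
    region_lobe: tuple[str, ...] | None = None
    _members: tuple[np.ndarray, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        vr = np.asarray(self.vertex_region, dtype=np.intp)
        object.__setattr__(self, "vertex_region", vr)
        n_regions = len(self.region_ids)
        if vr.ndim != 1:
            raise ValueError("vertex_region must be 1-D")
        if vr.size and (vr.min() < 0 or vr.max() >= n_regions):
            raise ValueError(
                f"vertex_region indices outside [0, {n_regions}): "
                f"min={vr.min()}, max={vr.max()}"
            )
        counts = np.bincount(vr, minlength=n_regions)
        if np.any(counts == 0):
            empty = [self.region_ids[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty regions not allowed: {empty}")
        if self.region_lobe is not None and len(self.region_lobe) != n_regions:
            raise ValueError("region_lobe must have one label per region")
        members = tuple(np.flatnonzero(vr == r) for r in range(n_regions))
        object.__setattr__(self, "_members", members)

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_region.size)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def vertices_of(self, region: int) -> np.ndarray:
        """Vertex indices belonging to region index ``region``."""
        return self._members[region]

    def lobe_of(self, region: int) -> str:
        if self.region_lobe is None:
            raise ValueError("parcellation carries no lobe labels")
        return self.region_lobe[region]

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        lobes = (
            [self.region_lobe[r] for r in self.vertex_region]
            if self.region_lobe is not None
            else [""] * self.n_vertices
        )
        return pd.DataFrame(
            {
                "vertex_id": np.arange(self.n_vertices),
                "region_id": [self.region_ids[r] for r in self.vertex_region],
                "lobe": lobes,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        df = df.sort_values("vertex_id")
        region_ids = tuple(pd.unique(df["region_id"]))
        index = {name: i for i, name in enumerate(region_ids)}
        vertex_region = np.array([index[name] for name in df["region_id"]])
        region_lobe = None
        if "lobe" in df.columns and df["lobe"].astype(str).str.len().any():
            lobe_by_region = df.groupby("region_id")["lobe"].first()
            region_lobe = tuple(str(lobe_by_region[name]) for name in region_ids)
        return cls(vertex_region, region_ids, region_lobe)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def contiguous_parcellation(
    n_vertices: int,
    n_regions: int,
    lobes: tuple[str, ...] = DEFAULT_LOBES,
    prefix: str = "R",
) -> Parcellation:
    """Split ``n_vertices`` into ``n_regions`` contiguous, near-equal regions.

    Regions are assigned to lobes round-robin so every lobe is populated
    whenever n_regions >= len(lobes).
    """
    if n_vertices < n_regions:
        raise ValueError("need at least one vertex per region")
    vertex_region = (np.arange(n_vertices) * n_regions) // n_vertices
    region_ids = tuple(f"{prefix}{i:03d}" for i in range(n_regions))
    region_lobe = tuple(lobes[i % len(lobes)] for i in range(n_regions))
    return Parcellation(vertex_region, region_ids, region_lobe)
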