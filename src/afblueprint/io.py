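"""File plumbing: HDF5 bundles, TSV tables, NIfTI volumes."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .blueprint import Blueprint, TractMapMatrix, WholeBrainMatrix
from .divergence import DivergenceMatrix
from .parcellation import Parcellation
from .synthetic import SpeciesData, SpeciesPair


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.array(list(values), dtype="S64"))


def _read_strings(group: h5py.Group, name: str) -> tuple[str, ...]:
    return tuple(s.decode() for s in group[name][()])


def save_species_pair(pair: SpeciesPair, path) -> None:
    """Write both species' C1/C2/parcellation/latent profiles to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for tag, sp in (("a", pair.a), ("b", pair.b)):
            g = f.create_group(tag)
            g.attrs["name"] = sp.spec.name
            g.create_dataset("C1", data=sp.c1.values, compression="gzip")
            g.create_dataset("C2", data=sp.c2.values, compression="gzip")
            g.create_dataset("latent_profiles", data=sp.latent_profiles)
            g.create_dataset("vertex_region", data=sp.parcellation.vertex_region)
            _write_strings(g, "region_ids", sp.parcellation.region_ids)
            _write_strings(g, "region_lobe", sp.parcellation.region_lobe or ())
            _write_strings(g, "tract_names", sp.c2.tract_names)
        plan = np.array(
            [(ra, rb, d) for ra, rb, d in pair.plan.pairs], dtype=float
        ).reshape(-1, 3)
        f.create_dataset("homology_plan", data=plan)


def save_blueprint(bp: Blueprint, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=bp.values, compression="gzip")
        f.create_dataset("valid", data=bp.valid)
        _write_strings(f, "tract_names", bp.tract_names)
        f.attrs["normalized"] = bp.normalized
        f.attrs["provenance"] = bp.provenance


def load_blueprint(path) -> Blueprint:
    with h5py.File(path, "r") as f:
        return Blueprint(
            f["values"][()],
            _read_strings(f, "tract_names"),
            normalized=bool(f.attrs["normalized"]),
            valid=f["valid"][()],
            provenance=str(f.attrs.get("provenance", "")),
        )


def save_divergence(dm: DivergenceMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=dm.values, compression="gzip")
        f.attrs["level"] = dm.level
        _write_strings(f, "row_ids", dm.row_ids)
        _write_strings(f, "col_ids", dm.col_ids)


def load_divergence(path) -> DivergenceMatrix:
    with h5py.File(path, "r") as f:
        return DivergenceMatrix(
            f["values"][()], str(f.attrs["level"]),
            _read_strings(f, "row_ids"), _read_strings(f, "col_ids"),
        )


def save_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a binary or density volume as NIfTI (identity affine by default)."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.float32), affine), str(path))


def load_mask(path, binarize: bool = False) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata())
    return data > 0.5 if binarize else data


def homology_table(pair: SpeciesPair) -> pd.DataFrame:
    """Homologous-pair table with species-tagged region ids and lobes."""
    rows = []
    for ra, rb, delta in pair.plan.pairs:
        rows.append({
            "region_a": pair.a.parcellation.region_ids[ra],
            "region_b": pair.b.parcellation.region_ids[rb],
            "delta": delta,
            "lobe": pair.a.parcellation.region_lobe[ra]
            if pair.a.parcellation.region_lobe else "",
        })
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix_tsv(path) -> np.ndarray:
    """Plain-text matrix reader for small cases (whitespace-separated)."""
    return np.loadtxt(path)
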