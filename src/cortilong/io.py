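"""Readers and writers for cohort tables, thickness matrices, meshes and
per-vertex fields.

Formats: cohort tables as CSV with a fixed header; thickness matrices as
delimited text or GIFTI functional files (one data array per scan); meshes
as GIFTI surfaces or OFF; vertex fields as GIFTI functional/shape files or
one-column text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import COHORT_COLUMNS
from .surface import SurfaceMesh

__all__ = [
    "read_cohort", "write_cohort",
    "read_thickness", "write_thickness",
    "read_mesh", "write_mesh_gifti",
    "read_field", "write_field",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table with the fixed column header (extra in-memory
    columns such as conversion_time are dropped)."""
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns {missing}")
    return cohort


def write_thickness(Y: np.ndarray, path) -> None:
    """Scans x vertices matrix as delimited text (.txt/.csv) or GIFTI
    functional file (.gii), one data array per scan."""
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        arrays = [nib.gifti.GiftiDataArray(row.astype(np.float32),
                                           intent="NIFTI_INTENT_NONE")
                  for row in np.asarray(Y)]
        nib.save(nib.gifti.GiftiImage(darrays=arrays), path)
    else:
        np.savetxt(path, Y, delimiter="\t")


def read_thickness(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(path)
        return np.vstack([d.data.astype(float) for d in img.darrays])
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def read_mesh(path, hemisphere=None) -> SurfaceMesh:
    """Load a triangle mesh from a GIFTI surface (.gii/.surf.gii) or OFF
    file. Vertex order is preserved."""
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(path)
        verts = faces = None
        for d in img.darrays:
            if d.intent == 1008:      # NIFTI_INTENT_POINTSET
                verts = d.data.astype(float)
            elif d.intent == 1009:    # NIFTI_INTENT_TRIANGLE
                faces = d.data.astype(np.int64)
        if verts is None or faces is None:
            raise ValueError(f"{path} is not a GIFTI surface")
    elif path.suffix.lower() == ".off":
        import trimesh

        m = trimesh.load(path, file_type="off", process=False)
        verts = np.asarray(m.vertices, dtype=float)
        faces = np.asarray(m.faces, dtype=np.int64)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    return SurfaceMesh(verts, faces, hemisphere=hemisphere)


def write_mesh_gifti(mesh: SurfaceMesh, path) -> None:
    import nibabel as nib

    da_v = nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                    intent="NIFTI_INTENT_POINTSET")
    da_f = nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                    intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[da_v, da_f]), path)


def write_field(values: np.ndarray, path) -> None:
    """Per-vertex scalar field as GIFTI shape (.gii) or one-column text."""
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        da = nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                      intent="NIFTI_INTENT_SHAPE")
        nib.save(nib.gifti.GiftiImage(darrays=[da]), path)
    else:
        np.savetxt(path, np.asarray(values))


def read_field(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(path)
        return img.darrays[0].data.astype(float)
    return np.loadtxt(path)
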