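"""File interfaces: NIfTI volumes, GIFTI surfaces and metric maps, tables.

Thin wrappers around nibabel keeping the package's in-memory containers
(:class:`~cortexdepth.surfaces.QVolume`, CorticalMesh, VertexMetricMap)
as the working currency.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .surfaces import CorticalMesh, QVolume, VertexMetricMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_surface",
    "load_surface",
    "save_metric",
    "load_metric",
    "save_cohort_table",
    "load_cohort_table",
]


def save_volume(volume: QVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))


def load_volume(path, tag: str = "qT1") -> QVolume:
    img = nib.load(str(path))
    return QVolume(np.asanyarray(img.dataobj, dtype=float), img.affine, tag)


def save_surface(mesh: CorticalMesh, path) -> None:
    """GIFTI surface file (.surf.gii) with pointset and triangle arrays."""
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    img = nib.gifti.GiftiImage(darrays=[coords, tris])
    img.meta["AnatomicalStructurePrimary"] = (
        "CortexLeft" if mesh.hemisphere == "left" else "CortexRight"
    )
    nib.save(img, str(path))


def load_surface(path, hemisphere: str | None = None) -> CorticalMesh:
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    if hemisphere is None:
        meta = dict(img.meta)
        hemisphere = (
            "left" if meta.get("AnatomicalStructurePrimary") == "CortexLeft" else "right"
        )
    return CorticalMesh(coords.astype(float), tris.astype(np.int64), hemisphere)


def save_metric(metric: VertexMetricMap, path) -> None:
    """GIFTI metric (func.gii) file, one scalar per vertex."""
    arr = nib.gifti.GiftiDataArray(
        metric.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
    )
    img = nib.gifti.GiftiImage(darrays=[arr])
    img.meta["Name"] = metric.name
    nib.save(img, str(path))


def load_metric(path, name: str = "") -> VertexMetricMap:
    img = nib.load(str(path))
    return VertexMetricMap(values=img.darrays[0].data.astype(float), name=name)


def save_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(str(path), index=False)


def load_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def save_subject(subject, out_dir) -> None:
    """Write one synthetic subject: surfaces, volumes, optional lesion mask."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    for hemi in subject.white:
        save_surface(subject.white[hemi], out / f"{hemi}.white.surf.gii")
        save_surface(subject.pial[hemi], out / f"{hemi}.pial.surf.gii")
        for mod in ("qT1", "qT2"):
            save_volume(subject.volumes[(mod, hemi)], out / f"{hemi}.{mod}.nii.gz")
        if subject.lesion_mask is not None:
            save_volume(subject.lesion_mask[hemi], out / f"{hemi}.lesion.nii.gz")
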