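"""Lesion z-score depth profiles against the control distribution.

A volumetric lesion mask is mapped onto the surface by the same ribbon
weighting used for qMRI sampling; the metric maps are residualized for
confounds (age, sex, vertexwise thickness and curvature) with the
nuisance coefficients of the joint group GLM; the patient's within-mask
mean residual at each depth — including a level 1 mm below the WM/GM
boundary probing the transmantle sign — is then z-scored against the
distribution of control within-mask means.  |z| > 2 flags a deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import DesignMatrix, glm_fit
from .surfaces import (
    CorticalMesh,
    DepthSurfaceSet,
    QVolume,
    VertexMetricMap,
    geodesic_distance,
    ribbon_sample,
)

__all__ = [
    "LesionSurfaceMask",
    "ZProfile",
    "map_lesion_to_surface",
    "residualize",
    "zscore_profile",
    "vertexwise_zmap",
    "distance_decay",
]


@dataclass
class LesionSurfaceMask:
    """Surface footprint of a volumetric lesion mask."""

    vertices: np.ndarray  # sorted vertex indices
    center_vertex: int  # geodesic medoid of the footprint
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        if len(self.vertices) == 0:
            raise ValueError("lesion surface mask is empty")


@dataclass
class ZProfile:
    """Depthwise z-score trajectory of one lesion for one modality."""

    levels: tuple[float, ...]
    z: np.ndarray
    modality: str
    significant: np.ndarray | None = None  # |z| > 2 per level
    threshold: float = 2.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.significant is None:
            self.significant = np.abs(self.z) > self.threshold


def map_lesion_to_surface(
    mask_volume: QVolume,
    depth_set: DepthSurfaceSet,
    weight_threshold: float = 0.5,
    band_halfwidth_fraction: float = 0.1,
) -> LesionSurfaceMask:
    """Project a binary lesion mask onto the surface.

    A vertex is part of the footprint if at any depth the ribbon-weighted
    overlap of its polyhedron with mask voxels exceeds
    ``weight_threshold``.  The lesion center is the geodesic medoid of
    the footprint (minimum summed geodesic distance to all its vertices).
    """
    data = mask_volume.data
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("lesion mask must be binary")
    hit = np.zeros(depth_set.white.n_vertices, dtype=bool)
    for lvl in depth_set.levels:
        m = ribbon_sample(mask_volume, depth_set, lvl, band_halfwidth_fraction)
        hit |= np.nan_to_num(m.values) > weight_threshold
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        raise ValueError("lesion mask maps to no surface vertex")
    white = depth_set.white
    sums = np.array(
        [geodesic_distance(white, int(v)).values[idx].sum() for v in idx]
    )
    center = int(idx[np.argmin(sums)])
    return LesionSurfaceMask(
        vertices=idx, center_vertex=center, hemisphere=white.hemisphere
    )


def residualize(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    vertex_nuisance: dict | None = None,
) -> np.ndarray:
    """Confound-removed maps Y - Z g-hat.

    g-hat are the nuisance coefficients estimated jointly with the group
    regressor (the unpermuted fit of Y = X b + Z g), so the group effect
    itself is *not* removed; residual means over controls (X = 0) are
    approximately zero per vertex.
    """
    design = DesignMatrix(Y=Y, X=X, Z=Z, vertex_nuisance=vertex_nuisance or {})
    fit = glm_fit(design)
    n, v = Y.shape
    extra = [np.asarray(m, dtype=float) for m in (vertex_nuisance or {}).values()]
    resid = np.asarray(Y, dtype=float) - design.Z @ fit.g[:, : design.Z.shape[1]].T
    for j, m in enumerate(extra):
        resid -= m * fit.g[:, design.Z.shape[1] + j][None, :]
    return resid


def zscore_profile(
    patient_resid: dict[float, np.ndarray],
    control_resid: dict[float, np.ndarray],
    lesion_mask: LesionSurfaceMask,
    levels=None,
    modality: str = "qT1",
) -> ZProfile:
    """Depthwise z of the patient's within-mask mean against controls.

    ``patient_resid[level]`` is the patient's residual map (v,);
    ``control_resid[level]`` the controls' maps (n_controls, v).  At each
    level the within-mask mean is taken per subject, and
    z = (patient - mean_controls) / sd_controls (ddof 1).  Levels with
    zero control SD yield NaN and are flagged, not silently zeroed.
    """
    if levels is None:
        levels = tuple(sorted(patient_resid))
    idx = lesion_mask.vertices
    zs = []
    for lvl in levels:
        ctrl = np.asarray(control_resid[lvl], dtype=float)
        if ctrl.shape[0] < 3:
            raise ValueError("need at least 3 controls")
        ctrl_means = ctrl[:, idx].mean(axis=1)
        pat_mean = float(np.asarray(patient_resid[lvl], dtype=float)[idx].mean())
        sd = float(ctrl_means.std(ddof=1))
        zs.append((pat_mean - ctrl_means.mean()) / sd if sd > 0 else np.nan)
    return ZProfile(levels=tuple(levels), z=np.array(zs), modality=modality)


def vertexwise_zmap(
    patient_resid: np.ndarray, control_resid: np.ndarray
) -> VertexMetricMap:
    """Per-vertex z of one patient's residual map against the controls."""
    mu = control_resid.mean(axis=0)
    sd = control_resid.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (patient_resid - mu) / sd
    return VertexMetricMap(values=z, name="z", units="SD")


def distance_decay(
    z_map: np.ndarray,
    mesh: CorticalMesh,
    center_vertex: int,
    bin_width_mm: float = 5.0,
    max_distance_mm: float | None = None,
):
    """Mean of a vertexwise map in geodesic-distance bins from a center.

    Bin edges sit at multiples of ``bin_width_mm``, left-closed
    right-open; empty bins are omitted, not zero-filled.  Used for the
    decay of |z| with distance from a lesion center (optionally zoomed to
    ``max_distance_mm``, e.g. 50 mm).

    Returns ``(bin_centers, means)``.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    d = geodesic_distance(mesh, center_vertex).values
    z = np.asarray(z_map, dtype=float)
    ok = np.isfinite(d) & np.isfinite(z)
    if max_distance_mm is not None:
        ok &= d < max_distance_mm
    d, z = d[ok], z[ok]
    bins = np.floor(d / bin_width_mm).astype(int)
    centers, means = [], []
    for b in np.unique(bins):
        centers.append((b + 0.5) * bin_width_mm)
        means.append(float(z[bins == b].mean()))
    return np.array(centers), np.array(means)
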