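"""Synthetic cortical qMRI cohorts.

Generates complete cohorts — paired white/pial hemisphere meshes, qT1/qT2
volumes with a depth-dependent laminar profile, covariates, focal lesions
with an optional transmantle extension, and group labels — with the
statistical structure the downstream analysis assumes, so every stage of
the pipeline is testable without clinical data.

Geometry is a reduced-scale digital phantom: each hemisphere is a closed
icosphere (left = mirror image of right, so left-right vertex
correspondence holds by construction), the cortical ribbon is the shell
between the white sphere and a pial surface displaced outward along vertex
normals by a smoothly varying thickness field.  Voxels take the value of
the laminar profile at their center's equivolume fraction (no
partial-volume mixing), which keeps an analytic oracle for every sampling
operation.

Sources of between-subject variation: additive voxel noise, a global
per-subject offset per modality (biological variability; this is the SD
scale lesion amplitudes are expressed in), a linear age slope, and a
smooth per-subject thickness field.  A "patient" group effect multiplies
the profile inside a depth window (default: superficial depths >= 0.6) by
(1 + amplitude), producing steeper white-to-pial gradients in patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .surfaces import (
    CorticalMesh,
    QVolume,
    RibbonGeometry,
    geodesic_distance,
    ribbon_geometry,
)

__all__ = [
    "DepthProfile",
    "GroupEffect",
    "LesionSpec",
    "CohortConfig",
    "SyntheticSubject",
    "make_hemisphere_pair",
    "make_slab_pair",
    "default_grid",
    "make_qmri_volume",
    "plant_group_effect",
    "plant_lesion",
    "make_cohort",
    "cohort_table",
]

DEFAULT_QT1_KNOTS = ((-0.2, 850.0), (0.0, 950.0), (1.0, 1900.0))
DEFAULT_QT2_KNOTS = ((-0.2, 55.0), (0.0, 60.0), (1.0, 90.0))


@dataclass(frozen=True)
class DepthProfile:
    """Piecewise-linear laminar profile, ms as a function of equivolume
    fraction.  Negative fractions (down to -0.2, in thickness units below
    the WM/GM boundary) carry the white-matter value; values increase
    toward the pial surface by default.
    """

    knots: tuple = DEFAULT_QT1_KNOTS

    def __post_init__(self) -> None:
        x = np.array([k[0] for k in self.knots])
        if len(x) < 2 or np.any(np.diff(x) <= 0):
            raise ValueError("knots must be strictly increasing in fraction")
        if x[0] > -0.2 or x[-1] < 1.0:
            raise ValueError("profile must cover fractions [-0.2, 1.0]")

    def __call__(self, fraction) -> np.ndarray:
        x = np.array([k[0] for k in self.knots])
        y = np.array([k[1] for k in self.knots])
        return np.interp(np.clip(fraction, x[0], x[-1]), x, y)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative patient effect inside a depth window.

    ``spatial_extent`` is "global" or a vertex index array (applied in
    both hemispheres via the mirrored correspondence).
    """

    depth_window: tuple[float, float] = (0.6, 1.0)
    amplitude: float = 0.05
    spatial_extent: object = "global"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        lo, hi = self.depth_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("depth window must be an increasing pair in [0, 1]")


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesion: geodesic patch around a center vertex, shifted by
    ``amplitude_sd`` per-subject-SD units, extending ``transmantle_depth_mm``
    below the WM/GM boundary."""

    center_vertex: int
    radius_mm: float = 8.0
    amplitude_sd: float = 4.0
    transmantle_depth_mm: float = 0.0
    hemisphere: str = "right"


@dataclass
class CohortConfig:
    """Generative conditions for one synthetic cohort.

    The cohort emulates a pediatric focal-epilepsy case-control study at
    reduced spatial scale: 20 patients vs 20 controls on 642-vertex
    icosphere hemispheres (subdivision 3), 1 mm isotropic voxels, and a
    +5% patient effect in the outer cortical depths.
    """

    n_patients: int = 20
    n_controls: int = 20
    mesh_subdivisions: int = 3
    white_radius: float = 20.0  # mm (reduced-scale phantom hemisphere)
    thickness_mean: float = 3.0  # mm
    thickness_sd: float = 0.25  # mm, smooth spatial + subject variation
    voxel_size: float = 1.0  # mm isotropic
    depth_profile_qT1: DepthProfile = field(default_factory=DepthProfile)
    depth_profile_qT2: DepthProfile = field(
        default_factory=lambda: DepthProfile(DEFAULT_QT2_KNOTS)
    )
    group_effect: GroupEffect = field(default_factory=GroupEffect)
    lesion_spec: LesionSpec | None = None
    n_lesion_patients: int = 0
    age_range: tuple[float, float] = (4.0, 18.0)
    age_slope_qT1: float = -5.0  # ms / year (maturation decrease)
    age_slope_qT2: float = -0.3  # ms / year
    noise_sd_qT1: float = 30.0  # ms additive voxel noise
    noise_sd_qT2: float = 2.0  # ms
    subject_offset_sd_qT1: float = 20.0  # ms global per-subject offset
    subject_offset_sd_qT2: float = 1.5  # ms
    mri_positive_fraction: float = 0.4  # patients tagged radiologically positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.thickness_mean <= 0:
            raise ValueError("thickness must be positive")

    def noise_sd(self, modality: str) -> float:
        return self.noise_sd_qT1 if modality == "qT1" else self.noise_sd_qT2

    def offset_sd(self, modality: str) -> float:
        return self.subject_offset_sd_qT1 if modality == "qT1" else self.subject_offset_sd_qT2

    def profile(self, modality: str) -> DepthProfile:
        return self.depth_profile_qT1 if modality == "qT1" else self.depth_profile_qT2


@dataclass
class SyntheticSubject:
    """One generated subject: meshes, volumes, covariates, optional lesion."""

    subject_id: str
    group: str  # {"patient", "control"}
    focus_side: str  # {"left", "right", "none"}
    age: float
    sex: str  # {"M", "F"}
    white: dict[str, CorticalMesh]
    pial: dict[str, CorticalMesh]
    volumes: dict[tuple[str, str], QVolume]  # (modality, hemisphere) -> volume
    geometry: dict[str, RibbonGeometry]
    lesion_mask: dict[str, QVolume] | None = None
    clinical: dict | None = None
    mri_status: str = "control"  # {"positive", "negative", "control"}
    reference_sd: dict = field(
        default_factory=lambda: {"qT1": 20.0, "qT2": 1.5}
    )

    def __post_init__(self) -> None:
        if self.group == "control" and (
            self.clinical is not None or self.focus_side != "none"
        ):
            raise ValueError("patient-only fields must be absent for controls")


# ---------------------------------------------------------------------------
# geometry


def _icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def make_hemisphere_pair(
    subdivisions: int,
    white_radius: float,
    thickness_field,
    seed: int | None = None,
    hemisphere: str = "right",
) -> tuple[CorticalMesh, CorticalMesh]:
    """Closed icosphere white surface and a pial surface displaced outward
    along vertex normals by the (scalar or per-vertex) thickness field.

    The left hemisphere is the mirror image (x -> -x) of the right built
    from the same thickness field, with winding flipped to keep outward
    orientation, so vertex i corresponds across hemispheres.
    """
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    unit, faces = _icosphere(subdivisions)
    thick = np.broadcast_to(np.asarray(thickness_field, dtype=float), (len(unit),)).copy()
    if np.any(thick <= 0):
        raise ValueError("thickness field must be strictly positive")
    wv = unit * white_radius
    pv = unit * (white_radius + thick[:, None])
    if hemisphere == "left":
        wv = wv * np.array([-1.0, 1.0, 1.0])
        pv = pv * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, [0, 2, 1]]
    white = CorticalMesh(wv, faces, hemisphere)
    pial = CorticalMesh(pv, faces, hemisphere)
    return white, pial


def make_slab_pair(
    nx: int = 12,
    ny: int = 12,
    spacing: float = 2.0,
    thickness: float = 3.0,
    hemisphere: str = "right",
) -> tuple[CorticalMesh, CorticalMesh]:
    """Flat-slab white/pial pair (open planar grid mesh, normals +z).

    The zero-curvature limit: equivolume and equidistant depths coincide,
    which makes this geometry the analytic oracle for sampling tests.
    """
    if thickness <= 0:
        raise ValueError("thickness must be strictly positive")
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    tris = np.asarray(tris, dtype=np.int64)
    white = CorticalMesh(verts, tris, hemisphere)
    pial = CorticalMesh(verts + np.array([0.0, 0.0, thickness]), tris, hemisphere)
    return white, pial


def default_grid(
    white: CorticalMesh, pial: CorticalMesh, voxel_size: float, pad_mm: float = 3.0
):
    """Axis-aligned voxel grid covering both surfaces plus padding.

    The padding also provides the margin needed for sub-WM sampling below
    the white surface.
    """
    verts = np.vstack([white.vertices, pial.vertices])
    lo = verts.min(axis=0) - pad_mm
    hi = verts.max(axis=0) + pad_mm
    shape = tuple(np.ceil((hi - lo) / voxel_size).astype(int) + 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return shape, affine


# ---------------------------------------------------------------------------
# volumes


def make_qmri_volume(
    white: CorticalMesh,
    pial: CorticalMesh,
    depth_profile: DepthProfile,
    noise_sd: float,
    voxel_size: float,
    seed: int = 0,
    tag: str = "qT1",
    grid: tuple | None = None,
    geometry: RibbonGeometry | None = None,
    offset: float = 0.0,
) -> QVolume:
    """Voxelize a laminar profile over the ribbon of one hemisphere.

    Each voxel inside the pial surface takes ``depth_profile`` at its
    center's equivolume fraction (below the white surface: the profile's
    white-matter tail), plus Gaussian noise and an optional global offset;
    voxels outside the pial surface are 0 background.  Bit-identical under
    a fixed seed.
    """
    if grid is None:
        shape, affine = default_grid(white, pial, voxel_size)
    else:
        shape, affine = grid
        lo = pial.vertices.min(axis=0)
        hi = pial.vertices.max(axis=0)
        vol = QVolume(np.zeros(shape), affine, tag)
        corner_lo = vol.voxel_to_world(np.zeros(3))
        corner_hi = vol.voxel_to_world(np.asarray(shape, dtype=float) - 1)
        if np.any(np.minimum(corner_lo, corner_hi) > lo) or np.any(
            np.maximum(corner_lo, corner_hi) < hi
        ):
            raise ValueError("voxel grid does not cover the mesh bounding box")
    if geometry is None:
        geometry = ribbon_geometry(white, pial, shape, affine)
    frac = geometry.fraction
    inside = np.isfinite(frac)
    data = np.zeros(shape)
    data[inside] = depth_profile(frac[inside]) + offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data[inside] += rng.normal(0.0, noise_sd, size=int(inside.sum()))
    return QVolume(data, affine, tag)


def plant_group_effect(
    subject: SyntheticSubject, group_effect: GroupEffect
) -> SyntheticSubject:
    """Scale ribbon voxels inside the effect's depth window by (1 + amplitude).

    Only valid for patients; applying to a control is an error.  With
    ``spatial_extent="global"`` the effect covers both hemispheres;
    otherwise only voxels attributed to the listed vertex trajectories.
    """
    if subject.group != "patient":
        raise ValueError("group effect applies to patients only")
    if group_effect.amplitude == 0.0:
        return subject
    lo, hi = group_effect.depth_window
    volumes = dict(subject.volumes)
    for (mod, hemi), vol in subject.volumes.items():
        geo = subject.geometry[hemi]
        sel = (geo.fraction >= lo) & (geo.fraction <= hi)
        if not isinstance(group_effect.spatial_extent, str):
            extent = np.zeros(subject.white[hemi].n_vertices, dtype=bool)
            extent[np.asarray(group_effect.spatial_extent, dtype=int)] = True
            sel &= extent[geo.nearest_vertex]
        data = vol.data.copy()
        data[sel] *= 1.0 + group_effect.amplitude
        volumes[(mod, hemi)] = QVolume(data, vol.affine, vol.tag)
    return dataclasses.replace(subject, volumes=volumes)


def plant_lesion(
    subject: SyntheticSubject, lesion_spec: LesionSpec, seed: int = 0
) -> SyntheticSubject:
    """Plant a focal lesion and record its mask volume.

    Voxels attributed to vertex trajectories within ``radius_mm`` geodesic
    distance of the center vertex, from ``transmantle_depth_mm`` below the
    WM/GM boundary up to the pial surface, are shifted by
    ``amplitude_sd`` times the cohort's per-subject SD for each modality.
    A lesion with a transmantle extension also marks voxels *intersected*
    by the column (half a voxel beyond the nominal depth); a purely
    cortical lesion stops at the boundary.
    """
    hemi = lesion_spec.hemisphere
    white = subject.white[hemi]
    if not 0 <= lesion_spec.center_vertex < white.n_vertices:
        raise ValueError("lesion center is not a valid vertex")
    gdist = geodesic_distance(white, lesion_spec.center_vertex).values
    if lesion_spec.radius_mm > np.nanmax(gdist[np.isfinite(gdist)]):
        raise ValueError("lesion radius exceeds hemisphere extent")
    in_patch = gdist <= lesion_spec.radius_mm
    geo = subject.geometry[hemi]
    depth_floor = -lesion_spec.transmantle_depth_mm
    if lesion_spec.transmantle_depth_mm > 0:
        vox = float(np.mean(np.linalg.norm(geo.affine[:3, :3], axis=0)))
        depth_floor -= 0.5 * vox
    sel = (
        in_patch[geo.nearest_vertex]
        & (geo.depth_mm >= depth_floor - 1e-9)
        & np.isfinite(geo.fraction)
    )
    volumes = dict(subject.volumes)
    for mod in ("qT1", "qT2"):
        vol = subject.volumes[(mod, hemi)]
        data = vol.data.copy()
        data[sel] += lesion_spec.amplitude_sd * subject.reference_sd[mod]
        volumes[(mod, hemi)] = QVolume(data, vol.affine, vol.tag)
    mask = {
        h: QVolume(
            (sel if h == hemi else np.zeros(subject.geometry[h].shape, dtype=bool)).astype(
                float
            ),
            subject.geometry[h].affine,
            "lesion",
        )
        for h in subject.white
    }
    return dataclasses.replace(subject, volumes=volumes, lesion_mask=mask)


# ---------------------------------------------------------------------------
# cohorts


def _subject_thickness(unit_normals: np.ndarray, mean: float, sd: float, rng) -> np.ndarray:
    """Smooth per-subject thickness: mean plus a random dipole pattern."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return np.maximum(mean + sd * unit_normals @ u, 0.5)


def make_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Generate the full cohort; bit-identical under a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    unit, _ = _icosphere(config.mesh_subdivisions)
    subjects: list[SyntheticSubject] = []
    n_total = config.n_patients + config.n_controls
    ages = rng.uniform(*config.age_range, size=n_total)
    sexes = rng.choice(["M", "F"], size=n_total)
    n_pos = int(round(config.mri_positive_fraction * config.n_patients))
    ref_sd = {"qT1": config.offset_sd("qT1"), "qT2": config.offset_sd("qT2")}

    for i in range(n_total):
        is_patient = i < config.n_patients
        sid = f"sub-{i:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        thick = _subject_thickness(
            unit, config.thickness_mean, config.thickness_sd, sub_rng
        )
        white, pial, geometry, volumes = {}, {}, {}, {}
        offsets = {
            "qT1": sub_rng.normal(0.0, config.offset_sd("qT1")),
            "qT2": sub_rng.normal(0.0, config.offset_sd("qT2")),
        }
        mean_age = 0.5 * (config.age_range[0] + config.age_range[1])
        age_eff = {
            "qT1": config.age_slope_qT1 * (ages[i] - mean_age),
            "qT2": config.age_slope_qT2 * (ages[i] - mean_age),
        }
        for hemi in ("left", "right"):
            w, p = make_hemisphere_pair(
                config.mesh_subdivisions, config.white_radius, thick, hemisphere=hemi
            )
            white[hemi], pial[hemi] = w, p
            shape, affine = default_grid(w, p, config.voxel_size)
            geometry[hemi] = ribbon_geometry(w, p, shape, affine)
            for mod in ("qT1", "qT2"):
                volumes[(mod, hemi)] = make_qmri_volume(
                    w,
                    p,
                    config.profile(mod),
                    config.noise_sd(mod),
                    config.voxel_size,
                    seed=int(sub_rng.integers(0, 2**31 - 1)),
                    tag=mod,
                    grid=(shape, affine),
                    geometry=geometry[hemi],
                    offset=offsets[mod] + age_eff[mod],
                )
        if is_patient:
            focus = "left" if rng.random() < 0.5 else "right"
            onset = float(rng.uniform(1.0, max(ages[i] - 0.5, 1.5)))
            clinical = {
                "age_at_onset": onset,
                "duration": float(max(ages[i] - onset, 0.0)),
                "seizures_per_year": float(rng.lognormal(3.0, 1.0)),
            }
            subject = SyntheticSubject(
                subject_id=sid,
                group="patient",
                focus_side=focus,
                age=float(ages[i]),
                sex=str(sexes[i]),
                white=white,
                pial=pial,
                volumes=volumes,
                geometry=geometry,
                clinical=clinical,
                mri_status="positive" if i < n_pos else "negative",
                reference_sd=ref_sd,
            )
            if config.group_effect.amplitude > 0:
                subject = plant_group_effect(subject, config.group_effect)
            if config.lesion_spec is not None and i < config.n_lesion_patients:
                subject = plant_lesion(subject, config.lesion_spec, seed=sub_seed)
        else:
            subject = SyntheticSubject(
                subject_id=sid,
                group="control",
                focus_side="none",
                age=float(ages[i]),
                sex=str(sexes[i]),
                white=white,
                pial=pial,
                volumes=volumes,
                geometry=geometry,
                mri_status="control",
                reference_sd=ref_sd,
            )
        subjects.append(subject)
    return subjects


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Covariate table, one row per subject."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "focus_side": s.focus_side,
            "age": s.age,
            "sex": s.sex,
            "mri_status": s.mri_status,
            "age_at_onset": np.nan,
            "duration": np.nan,
            "seizures_per_year": np.nan,
        }
        if s.clinical:
            row.update(s.clinical)
        rows.append(row)
    return pd.DataFrame(rows)
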