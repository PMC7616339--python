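"""Per-subject depthwise feature assembly.

Smooths the qMRI volumes, samples them at the equivolume depths with
ribbon weighting, forms the intracortical gradient (value at 80% depth
minus value at 20% depth — an index of depthwise microstructural
organization), and normalizes laterality by swapping hemispheres for
patients with a right-sided seizure focus so the ipsilateral hemisphere
is always stored first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .surfaces import (
    CorticalMesh,
    DepthSurfaceSet,
    QVolume,
    build_depth_set,
    ribbon_sample,
)

__all__ = [
    "DepthFeatureSet",
    "smooth_volume",
    "extract_depth_features",
    "flip_hemispheres",
    "HEMI_ORDER",
]

#: storage order of hemisphere blocks in stacked arrays; after flipping,
#: index 0 is the hemisphere ipsilateral to the seizure focus.
HEMI_ORDER = ("left", "right")

DEFAULT_FRACTIONS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class DepthFeatureSet:
    """Depthwise per-vertex maps for one subject and one modality.

    ``maps[hemi]`` has shape (n_levels, n_vertices); ``levels`` are sorted
    (sub-WM level, expressed as negative mm, first).  ``gradient[hemi]``
    is map(0.8) - map(0.2).  ``flipped`` records laterality normalization.
    """

    subject_id: str
    modality: str
    levels: tuple[float, ...]
    maps: dict[str, np.ndarray]
    gradient: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    flipped: bool = False

    def level_index(self, level: float) -> int:
        return self.levels.index(level)

    def map_at(self, level: float, hemi: str) -> np.ndarray:
        return self.maps[hemi][self.level_index(level)]

    def stacked(self, level: float) -> np.ndarray:
        """Both hemispheres concatenated in storage order (ipsi first if
        flipped)."""
        i = self.level_index(level)
        return np.concatenate([self.maps[h][i] for h in HEMI_ORDER])

    def stacked_gradient(self) -> np.ndarray:
        return np.concatenate([self.gradient[h] for h in HEMI_ORDER])


def smooth_volume(
    volume: QVolume, sigma_mm: float, mask: np.ndarray | None = None
) -> QVolume:
    """Gaussian smoothing with sigma in millimetres (sigma 0 = identity).

    At the native 1 mm isotropic resolution a sigma in voxels and in mm
    coincide; anisotropic grids get per-axis sigmas in voxel units.

    With ``mask``, voxels outside it are treated as missing rather than
    zero (normalized convolution: the masked data and the mask indicator
    are smoothed and their ratio taken inside the mask), which avoids
    dragging boundary values toward the background of masked qMRI maps.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return QVolume(volume.data.copy(), volume.affine.copy(), volume.tag)
    sig_vox = sigma_mm / volume.voxel_size
    if mask is None:
        return QVolume(
            gaussian_filter(volume.data, sigma=sig_vox), volume.affine, volume.tag
        )
    m = mask.astype(float)
    num = gaussian_filter(volume.data * m, sigma=sig_vox)
    den = gaussian_filter(m, sigma=sig_vox)
    out = np.zeros_like(volume.data)
    inside = (den > 1e-12) & mask
    out[inside] = num[inside] / den[inside]
    return QVolume(out, volume.affine, volume.tag)


def extract_depth_features(
    subject,
    modality: str,
    fractions=DEFAULT_FRACTIONS,
    sub_wm_mm: float = 0.0,
    sigma_mm: float = 0.4,
    band_halfwidth_fraction: float = 0.1,
    gradient_levels: tuple[float, float] = (0.2, 0.8),
) -> DepthFeatureSet:
    """Smooth, sample at each depth, and form the gradient map.

    ``subject`` provides white/pial meshes per hemisphere and volumes
    keyed by (modality, hemisphere) (see ``synthetic.SyntheticSubject``;
    any object with those attributes works).
    """
    maps: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    gradient: dict[str, np.ndarray] = {}
    levels: tuple[float, ...] | None = None
    for hemi in HEMI_ORDER:
        white: CorticalMesh = subject.white[hemi]
        pial: CorticalMesh = subject.pial[hemi]
        depth_set: DepthSurfaceSet = build_depth_set(white, pial, fractions, sub_wm_mm)
        raw = subject.volumes[(modality, hemi)]
        # zero voxels are masked background (outside the fitted brain mask)
        vol = smooth_volume(raw, sigma_mm, mask=raw.data != 0)
        rows = []
        ok = np.ones(white.n_vertices, dtype=bool)
        for lvl in depth_set.levels:
            m = ribbon_sample(vol, depth_set, lvl, band_halfwidth_fraction)
            rows.append(m.values)
            ok &= m.valid
        maps[hemi] = np.vstack(rows)
        valid[hemi] = ok
        levels = depth_set.levels
        lo, hi = gradient_levels
        gradient[hemi] = maps[hemi][levels.index(hi)] - maps[hemi][levels.index(lo)]
    return DepthFeatureSet(
        subject_id=getattr(subject, "subject_id", ""),
        modality=modality,
        levels=levels,
        maps=maps,
        gradient=gradient,
        valid=valid,
    )


def flip_hemispheres(features: DepthFeatureSet, focus_side: str) -> DepthFeatureSet:
    """Swap hemisphere blocks for right-focus subjects (ipsilateral first).

    Left-focus subjects and controls pass through unchanged; flipping
    twice is the identity.  Relies on the homologous left-right vertex
    correspondence of the mirrored meshes.
    """
    if focus_side not in ("left", "right", "none"):
        raise ValueError(f"unknown focus side {focus_side!r}")
    if focus_side != "right":
        return features
    a, b = HEMI_ORDER
    if features.maps[a].shape != features.maps[b].shape:
        raise ValueError("hemisphere maps must have matching vertex counts")
    return dataclasses.replace(
        features,
        maps={a: features.maps[b], b: features.maps[a]},
        gradient={a: features.gradient[b], b: features.gradient[a]},
        valid={a: features.valid[b], b: features.valid[a]},
        flipped=not features.flipped,
    )
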