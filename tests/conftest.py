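"""Shared fixtures: small meshes and two session-scoped synthetic cohorts
(one with the planted superficial group effect, one null with planted
focal lesions), with depthwise features extracted once."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from cortexdepth.features import (
    HEMI_ORDER,
    DepthFeatureSet,
    extract_depth_features,
    flip_hemispheres,
)
from cortexdepth.inference import SurfaceGraph
from cortexdepth.surfaces import vertex_curvature, vertex_thickness
from cortexdepth.synthetic import (
    CohortConfig,
    GroupEffect,
    LesionSpec,
    make_cohort,
    make_hemisphere_pair,
    make_slab_pair,
    cohort_table,
    plant_lesion,
)

SUB_WM_MM = 1.0


@dataclass
class CohortBundle:
    config: CohortConfig
    subjects: list
    table: pd.DataFrame
    features: dict[str, list[DepthFeatureSet]]  # laterality-flipped
    thickness: np.ndarray  # (n, 2 * n_vertices), flipped like the features
    curvature: np.ndarray
    graph: SurfaceGraph


def _bundle(config: CohortConfig, lesions: dict[int, LesionSpec] | None = None):
    subjects = make_cohort(config)
    if lesions:
        for i, spec in lesions.items():
            subjects[i] = plant_lesion(subjects[i], spec)
    table = cohort_table(subjects)
    features = {"qT1": [], "qT2": []}
    thick_rows, curv_rows = [], []
    for sub in subjects:
        for mod in ("qT1", "qT2"):
            fs = extract_depth_features(sub, mod, sub_wm_mm=SUB_WM_MM)
            features[mod].append(flip_hemispheres(fs, sub.focus_side))
        th = np.concatenate(
            [vertex_thickness(sub.white[h], sub.pial[h]).values for h in HEMI_ORDER]
        )
        cu = np.concatenate(
            [
                np.nan_to_num(vertex_curvature(sub.white[h]).values)
                for h in HEMI_ORDER
            ]
        )
        if sub.focus_side == "right":  # keep nuisance aligned with flipped maps
            half = len(th) // 2
            th = np.r_[th[half:], th[:half]]
            cu = np.r_[cu[half:], cu[:half]]
        thick_rows.append(th)
        curv_rows.append(cu)
    graph = SurfaceGraph([subjects[0].white[h] for h in HEMI_ORDER])
    return CohortBundle(
        config=config,
        subjects=subjects,
        table=table,
        features=features,
        thickness=np.vstack(thick_rows),
        curvature=np.vstack(curv_rows),
        graph=graph,
    )


@pytest.fixture(scope="session")
def effect_cohort() -> CohortBundle:
    """Default conditions: 20 patients vs 20 controls, +5% effect at
    depths >= 0.6."""
    return _bundle(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort() -> CohortBundle:
    """Same conditions with amplitude 0 (patients exchangeable with
    controls) and six planted +4 SD lesions: three with a 1 mm
    transmantle extension (patients 0-2), three confined to gray matter
    (patients 3-5)."""
    cfg = CohortConfig(seed=13, group_effect=GroupEffect(amplitude=0.0))
    lesions = {
        i: LesionSpec(
            center_vertex=17, radius_mm=8.0, amplitude_sd=4.0,
            transmantle_depth_mm=1.0 if i < 3 else 0.0, hemisphere="right",
        )
        for i in range(6)
    }
    return _bundle(cfg, lesions)


@pytest.fixture(scope="session")
def sphere_pair():
    """Subdivision-3 icosphere pair, 49 mm white radius, 3 mm thickness."""
    return make_hemisphere_pair(3, 49.0, 3.0)


@pytest.fixture(scope="session")
def slab_pair():
    """Flat slab, 3 mm thick, 2 mm vertex spacing."""
    return make_slab_pair(14, 14, 2.0, 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
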