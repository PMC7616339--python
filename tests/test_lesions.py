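"""Lesion surface mapping, confound residualization, z-score profiles,
transmantle sensitivity, and distance-decay curves."""

import numpy as np
import pytest

from cortexdepth.features import HEMI_ORDER
from cortexdepth.lesions import (
    LesionSurfaceMask,
    distance_decay,
    map_lesion_to_surface,
    residualize,
    vertexwise_zmap,
    zscore_profile,
)
from cortexdepth.surfaces import build_depth_set, geodesic_distance

SUB_WM_MM = 1.0
LEVELS = (-1.0, 0.2, 0.4, 0.6, 0.8)


# ---------------------------------------------------------------------------
# helpers building residual maps from the null cohort (lesions planted on
# patients 0-2: transmantle 1 mm, and 3-5: gray-matter only; see conftest)


def _stacked_maps(bundle, mod, level):
    return np.vstack([f.stacked(level) for f in bundle.features[mod]])


def _residual_maps(bundle, mod):
    """Residualize per level against intercept+age+sex+thickness+curvature."""
    tab = bundle.table
    X = (tab.group.values == "patient").astype(float)
    age = tab.age.values.astype(float)
    sex = (tab.sex.values == "M").astype(float)
    Z = np.column_stack([np.ones(len(X)), age - age.mean(), sex])
    vn = {"thickness": bundle.thickness, "curvature": bundle.curvature}
    out = {}
    for lvl in LEVELS:
        Y = np.nan_to_num(_stacked_maps(bundle, mod, lvl))
        out[lvl] = residualize(Y, X, Z, vn)
    return out


@pytest.fixture(scope="module")
def lesion_setup(null_cohort):
    sub = null_cohort.subjects[0]
    ds = build_depth_set(
        sub.white["right"], sub.pial["right"], (0.2, 0.4, 0.6, 0.8), SUB_WM_MM
    )
    mask = map_lesion_to_surface(sub.lesion_mask["right"], ds)
    # features are flipped ipsi-first; map the right-hemisphere footprint
    # into the stacked array of each subject
    n_v = sub.white["right"].n_vertices

    def stacked_idx(subject_focus):
        # right-hemisphere block sits second unless the subject was flipped
        offset = 0 if subject_focus == "right" else n_v
        return mask.vertices + offset

    resid = {m: _residual_maps(null_cohort, m) for m in ("qT1", "qT2")}
    return null_cohort, mask, stacked_idx, resid, n_v


class TestLesionMapping:
    def test_planted_patch_footprint_area(self, lesion_setup):
        bundle, mask, _, _, _ = lesion_setup
        sub = bundle.subjects[0]
        white = sub.white["right"]
        # footprint should cover roughly the geodesic disc planted (8 mm)
        d = geodesic_distance(white, 17).values
        area_patch = white.vertex_areas[d <= 8.0].sum()
        area_found = white.vertex_areas[mask.vertices].sum()
        assert area_found == pytest.approx(area_patch, rel=0.25)

    def test_center_is_geodesic_medoid_near_seed(self, lesion_setup):
        bundle, mask, _, _, _ = lesion_setup
        white = bundle.subjects[0].white["right"]
        d = geodesic_distance(white, 17).values
        assert d[mask.center_vertex] < 4.0  # within ~a vertex spacing of seed

    def test_whole_ribbon_mask_selects_all_vertices(self, null_cohort):
        sub = null_cohort.subjects[6]
        vol = sub.volumes[("qT1", "right")]
        full = vol.data != 0  # entire ribbon + WM interior
        from cortexdepth.surfaces import QVolume

        ds = build_depth_set(sub.white["right"], sub.pial["right"], (0.2, 0.8))
        m = map_lesion_to_surface(QVolume(full.astype(float), vol.affine, "mask"), ds)
        assert len(m.vertices) == sub.white["right"].n_vertices

    def test_empty_mask_rejected(self, null_cohort):
        sub = null_cohort.subjects[6]
        vol = sub.volumes[("qT1", "right")]
        from cortexdepth.surfaces import QVolume

        ds = build_depth_set(sub.white["right"], sub.pial["right"], (0.2, 0.8))
        with pytest.raises(ValueError):
            map_lesion_to_surface(
                QVolume(np.zeros_like(vol.data), vol.affine, "mask"), ds
            )
        with pytest.raises(ValueError):
            LesionSurfaceMask(vertices=np.array([], dtype=int), center_vertex=0)


class TestResidualize:
    def test_constant_y_intercept_only_gives_zero(self):
        Y = np.full((10, 4), 7.5)
        X = np.r_[np.ones(5), np.zeros(5)]
        resid = residualize(Y, X, np.ones((10, 1)))
        # intercept absorbs the constant; controls' residuals vanish
        assert np.allclose(resid[X == 0], 0.0, atol=1e-10)

    def test_pure_age_effect_removed_exactly(self, rng):
        n = 12
        age = rng.uniform(4, 18, size=n)
        X = np.r_[np.ones(6), np.zeros(6)]
        Y = np.tile(3.0 * age, (5, 1)).T
        Z = np.column_stack([np.ones(n), age])
        resid = residualize(Y, X, Z)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        n, v = 15, 6
        Y = rng.normal(size=(n, v))
        X = rng.normal(size=n)
        Z = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        vn = {"thickness": rng.normal(size=(n, v))}
        resid = residualize(Y, X, Z, vn)
        # joint-fit residuals Y - Zg keep the Xb part; subtract it for the
        # orthogonality check of the pure LS residual
        from cortexdepth.inference import DesignMatrix, glm_fit

        fit = glm_fit(DesignMatrix(Y=Y, X=X, Z=Z, vertex_nuisance=vn))
        pure = resid - X[:, None] * fit.b[None, :]
        for j in range(v):
            Dj = np.column_stack([Z, vn["thickness"][:, j]])
            assert np.abs(Dj.T @ pure[:, j]).max() < 1e-8

    def test_control_residual_mean_near_zero(self, lesion_setup):
        bundle, _, _, resid, _ = lesion_setup
        ctrl = bundle.table.group.values == "control"
        for lvl in LEVELS:
            m = resid["qT1"][lvl][ctrl].mean(axis=0)
            sd = resid["qT1"][lvl][ctrl].std(axis=0).mean()
            assert np.abs(m).mean() < 0.2 * sd + 1e-9


class TestZProfiles:
    def test_planted_lesion_exceeds_two_sd_at_affected_depths(self, lesion_setup):
        bundle, mask, stacked_idx, resid, _ = lesion_setup
        ctrl = bundle.table.group.values == "control"
        pat0 = bundle.subjects[0]
        idx = stacked_idx(pat0.focus_side)
        smask = LesionSurfaceMask(vertices=idx, center_vertex=int(idx[0]))
        for mod in ("qT1", "qT2"):
            prof = zscore_profile(
                {l: resid[mod][l][0] for l in LEVELS},
                {l: resid[mod][l][ctrl] for l in LEVELS},
                smask,
                levels=LEVELS,
                modality=mod,
            )
            z = dict(zip(prof.levels, prof.z))
            for lvl in (0.2, 0.4, 0.6, 0.8):
                assert z[lvl] > 2.0
            assert prof.significant[list(prof.levels).index(0.8)]

    def test_transmantle_vs_gm_only_at_sub_wm_level(self, lesion_setup):
        """Across the planted lesions, the 1 mm transmantle columns deviate
        at the -1 mm level and the gray-matter-only lesions do not; the
        per-lesion z rides on subject-level variability, so the contrast is
        assessed on the mean over the three lesions of each kind."""
        bundle, mask, stacked_idx, resid, _ = lesion_setup
        ctrl = bundle.table.group.values == "control"
        zs = {}
        for i in range(6):  # 0-2: transmantle 1 mm, 3-5: GM-only
            idx = stacked_idx(bundle.subjects[i].focus_side)
            smask = LesionSurfaceMask(vertices=idx, center_vertex=int(idx[0]))
            prof = zscore_profile(
                {l: resid["qT1"][l][i] for l in LEVELS},
                {l: resid["qT1"][l][ctrl] for l in LEVELS},
                smask,
                levels=LEVELS,
            )
            zs[i] = dict(zip(prof.levels, prof.z))
        z_tm = np.mean([zs[i][-1.0] for i in range(3)])
        z_gm = np.mean([zs[i][-1.0] for i in range(3, 6)])
        assert z_tm > 2.0  # transmantle deviates 1 mm below WM
        assert abs(z_gm) < 2.0  # GM-only does not
        assert min(zs[i][0.8] for i in range(3, 6)) > 2.0  # but shows in cortex

    def test_leave_one_out_control_profiles_center_on_zero(self, lesion_setup):
        bundle, mask, stacked_idx, resid, n_v = lesion_setup
        ctrl_idx = np.flatnonzero(bundle.table.group.values == "control")
        idx = mask.vertices + n_v  # unflipped controls: right block second
        smask = LesionSurfaceMask(vertices=idx, center_vertex=int(idx[0]))
        zs = []
        for i in ctrl_idx:
            rest = ctrl_idx[ctrl_idx != i]
            prof = zscore_profile(
                {l: resid["qT1"][l][i] for l in LEVELS},
                {l: resid["qT1"][l][rest] for l in LEVELS},
                smask,
                levels=LEVELS,
            )
            zs.append(prof.z)
        assert np.abs(np.mean(zs, axis=0)).max() < 0.3

    def test_too_few_controls_rejected(self, lesion_setup):
        bundle, mask, _, resid, n_v = lesion_setup
        idx = mask.vertices + n_v
        smask = LesionSurfaceMask(vertices=idx, center_vertex=int(idx[0]))
        with pytest.raises(ValueError):
            zscore_profile(
                {l: resid["qT1"][l][0] for l in LEVELS},
                {l: resid["qT1"][l][:2] for l in LEVELS},
                smask,
                levels=LEVELS,
            )


class TestDistanceDecay:
    def test_constant_map_gives_flat_curve(self, null_cohort):
        white = null_cohort.subjects[0].white["right"]
        z = np.full(white.n_vertices, 1.7)
        centers, means = distance_decay(z, white, 17, bin_width_mm=5.0)
        assert np.allclose(means, 1.7, atol=1e-12)
        # left-closed, right-open bins at multiples of the width
        assert np.allclose(centers % 5.0, 2.5, atol=1e-9)

    def test_indicator_patch_decays_beyond_radius(self, null_cohort):
        white = null_cohort.subjects[0].white["right"]
        d = geodesic_distance(white, 17).values
        z = np.where(d <= 8.0, 5.0, 0.0)
        centers, means = distance_decay(z, white, 17, bin_width_mm=4.0)
        assert means[0] == pytest.approx(5.0, abs=1e-9)
        assert np.all(means[centers > 14.0] == 0.0)

    def test_zoomed_view_restricts_range(self, null_cohort):
        white = null_cohort.subjects[0].white["right"]
        z = np.ones(white.n_vertices)
        centers, _ = distance_decay(z, white, 17, 5.0, max_distance_mm=50.0)
        assert centers.max() < 50.0

    def test_vertexwise_zmap_standardizes_controls(self, rng):
        ctrl = rng.normal(5.0, 2.0, size=(200, 30))
        pat = ctrl[0]
        z = vertexwise_zmap(pat, ctrl[1:])
        assert np.abs(z.values).max() < 5.0
        assert abs(z.values.mean()) < 1.0
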