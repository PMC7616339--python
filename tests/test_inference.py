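"""GLM against hand linear algebra, TFCE against brute-force threshold
integration, permutation inference against exhaustive enumeration, and
FWE monotonicity."""

import itertools

import numpy as np
import pytest
from cortexdepth.inference import (
    DesignMatrix,
    SurfaceGraph,
    VertexGLM,
    clinical_association,
    fwe_across,
    glm_fit,
    interaction_screen,
    permutation_test,
    tfce,
)
from cortexdepth.synthetic import make_hemisphere_pair
from oracles import brute_force_tfce


@pytest.fixture(scope="module")
def small_graph():
    mesh, _ = make_hemisphere_pair(2, 20.0, 2.5)  # 162 vertices
    return SurfaceGraph(mesh)


@pytest.fixture(scope="module")
def tiny_graph():
    mesh, _ = make_hemisphere_pair(1, 20.0, 2.5)  # 42 vertices
    return SurfaceGraph(mesh)


class TestGLM:
    def test_exact_coefficient_recovery(self, tiny_graph, rng):
        n = 12
        X = rng.normal(size=n)
        Y = np.tile(2.0 * X, (tiny_graph.n_vertices, 1)).T
        fit = glm_fit(DesignMatrix(Y=Y, X=X))
        assert np.allclose(fit.b, 2.0, atol=1e-10)

    def test_orthogonal_regressor_gives_small_t(self, rng):
        n = 2000
        X = rng.normal(size=n)
        Y = rng.normal(size=(n, 3))
        fit = glm_fit(DesignMatrix(Y=Y, X=X))
        assert np.all(np.abs(fit.t) < 4.0)

    def test_matches_hand_linear_algebra(self, rng):
        n, v = 10, 5
        Y = rng.normal(size=(n, v))
        X = rng.normal(size=n)
        Z = np.column_stack([np.ones(n), rng.normal(size=n)])
        vz = {"thickness": rng.normal(size=(n, v))}
        d = DesignMatrix(Y=Y, X=X, Z=Z, vertex_nuisance=vz)
        fit = glm_fit(d)
        glm = VertexGLM(d)
        t_fwl = glm.t_for(X)
        for j in range(v):
            D = np.column_stack([X, Z, vz["thickness"][:, j]])
            beta = np.linalg.lstsq(D, Y[:, j], rcond=None)[0]
            res = Y[:, j] - D @ beta
            s2 = res @ res / (n - D.shape[1])
            t_ref = beta[0] / np.sqrt(s2 * np.linalg.inv(D.T @ D)[0, 0])
            assert fit.t[j] == pytest.approx(t_ref, abs=1e-8)
            assert t_fwl[j] == pytest.approx(t_ref, abs=1e-8)

    def test_rank_deficient_vertex_flagged(self, rng):
        n = 8
        X = rng.normal(size=n)
        Y = rng.normal(size=(n, 2))
        vz = {"dup": np.tile(X, (2, 1)).T.copy()}  # collinear with X everywhere
        fit = glm_fit(DesignMatrix(Y=Y, X=X, vertex_nuisance=vz))
        assert not fit.valid.any()
        assert np.all(fit.t == 0.0)


class TestTFCE:
    def test_zero_map_gives_zero(self, small_graph):
        assert np.all(tfce(np.zeros(small_graph.n_vertices), small_graph) == 0)

    def test_single_vertex_closed_form(self, small_graph):
        """An isolated suprathreshold vertex accumulates its own area over
        the threshold grid: sum of a^E h^H dh."""
        s = np.zeros(small_graph.n_vertices)
        s[7] = 3.0
        out = tfce(s, small_graph, E=1.0, H=2.0)
        dh = 3.0 / 100
        grid = np.arange(dh, 3.0 + 0.5 * dh, dh)
        expect = small_graph.vertex_areas[7] * np.sum(grid**2 * dh)
        assert out[7] == pytest.approx(expect, rel=1e-9)
        assert np.all(out[np.arange(len(out)) != 7] == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, small_graph, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=small_graph.n_vertices)
        fast = tfce(s, small_graph)
        slow = brute_force_tfce(s, small_graph)
        assert np.abs(fast - slow).max() <= 0.01 * np.abs(slow).max()

    def test_negative_tail_antisymmetric(self, small_graph, rng):
        s = rng.normal(size=small_graph.n_vertices)
        assert np.allclose(tfce(-s, small_graph), -tfce(s, small_graph), atol=1e-9)

    def test_invalid_dh_rejected(self, small_graph):
        with pytest.raises(ValueError):
            tfce(np.ones(small_graph.n_vertices), small_graph, dh=-0.5)


class TestPermutation:
    def test_exhaustive_matches_manual_enumeration(self, tiny_graph, rng):
        """4-vs-4 toy: p-values equal brute-force enumeration over all 70
        distinct label arrangements."""
        n = 8
        X = np.r_[np.ones(4), np.zeros(4)]
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        Y[:4] += 0.8  # a real signal so p-values spread out
        d = DesignMatrix(Y=Y, X=X)
        res = permutation_test(d, tiny_graph, n_perm=500, seed=3)
        assert res.exhaustive and res.n_perm == 69

        glm = VertexGLM(d)
        arrangements = sorted(set(itertools.permutations(X.tolist())))
        assert len(arrangements) == 70
        stats = np.array(
            [tfce(glm.t_for(np.array(a)), tiny_graph) for a in arrangements]
        )
        obs = tfce(glm.t_for(X), tiny_graph)
        p_manual = (stats >= obs[None, :] - 1e-12).mean(axis=0)
        assert np.allclose(res.p_uncorrected, p_manual, atol=1e-12)
        p_fwe_manual = (stats.max(axis=1)[:, None] >= obs[None, :] - 1e-12).mean(axis=0)
        assert np.allclose(res.p_fwe, p_fwe_manual, atol=1e-12)

    def test_same_seed_identical_result(self, tiny_graph, rng):
        n = 16
        X = rng.normal(size=n)
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        d = DesignMatrix(Y=Y, X=X)
        a = permutation_test(d, tiny_graph, n_perm=50, seed=9)
        b = permutation_test(d, tiny_graph, n_perm=50, seed=9)
        assert np.array_equal(a.p_uncorrected, b.p_uncorrected)
        assert np.array_equal(a.p_fwe, b.p_fwe)
        assert a.schedule_id == b.schedule_id

    def test_p_never_zero_and_minimum_attainable(self, tiny_graph, rng):
        n = 20
        X = np.r_[np.ones(10), np.zeros(10)]
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        Y[:10] += 5.0  # overwhelming effect
        res = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=99, seed=0)
        assert res.p_uncorrected.min() == pytest.approx(1.0 / 100.0)
        assert np.all(res.p_uncorrected > 0)

    def test_constant_shift_of_y_invariant(self, tiny_graph, rng):
        n = 14
        X = rng.normal(size=n)
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        d1 = DesignMatrix(Y=Y, X=X)
        d2 = DesignMatrix(Y=Y + 123.4, X=X)
        r1 = permutation_test(d1, tiny_graph, n_perm=30, seed=2)
        r2 = permutation_test(d2, tiny_graph, n_perm=30, seed=2)
        assert np.allclose(r1.t, r2.t, atol=1e-8)
        assert np.allclose(r1.p_uncorrected, r2.p_uncorrected, atol=1e-12)

    def test_p_ordering_monotone(self, tiny_graph, rng):
        n = 12
        X = rng.normal(size=n)
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        res = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=60, seed=1)
        res.check_monotone()
        assert np.all(res.p_fwe >= res.p_uncorrected - 1e-12)


class TestFWEAcross:
    def test_single_result_degenerate_family(self, tiny_graph, rng):
        n = 12
        X = np.r_[np.ones(6), np.zeros(6)]
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        res = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=200, seed=4)
        (out,) = fwe_across([res])
        assert np.allclose(out.p_fwe_across, out.p_fwe, atol=1e-12)

    def test_duplicated_result_monotone(self, tiny_graph, rng):
        n = 12
        X = np.r_[np.ones(6), np.zeros(6)]
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        r1 = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=200, seed=4)
        r2 = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=200, seed=4)
        fwe_across([r1, r2])
        assert np.all(r1.p_fwe_across >= r1.p_fwe - 1e-12)
        assert np.all((r1.p_fwe_across >= 0) & (r1.p_fwe_across <= 1))

    def test_unsynchronized_schedules_rejected(self, tiny_graph, rng):
        n = 12
        X = np.r_[np.ones(6), np.zeros(6)]
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        r1 = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=100, seed=4)
        r2 = permutation_test(DesignMatrix(Y=Y, X=X), tiny_graph, n_perm=100, seed=5)
        with pytest.raises(ValueError):
            fwe_across([r1, r2])


class TestScreens:
    def test_interaction_invariant_to_covariate_origin(self, tiny_graph, rng):
        # centering makes the screen independent of the age/group coding origin
        n = 20
        group = np.r_[np.ones(10), np.zeros(10)]
        age = rng.uniform(4, 18, size=n)
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        r1 = interaction_screen(Y, group, age, graph=tiny_graph, n_perm=30, seed=0)
        r2 = interaction_screen(Y, group + 5.0, age - 11.0, graph=tiny_graph,
                                n_perm=30, seed=0)
        assert r1.alternative == "two-sided"
        assert np.allclose(r1.t, r2.t, atol=1e-8)

    def test_planted_interaction_detected(self, tiny_graph, rng):
        n = 40
        group = np.r_[np.ones(20), np.zeros(20)]
        age = rng.uniform(4, 18, size=n)
        x = (group - group.mean()) * (age - age.mean())
        Y = rng.normal(size=(n, tiny_graph.n_vertices)) * 0.3
        Y += 2.0 * x[:, None]
        res = interaction_screen(Y, group, age, graph=tiny_graph, n_perm=199, seed=0)
        assert res.p_fwe.min() <= 0.01

    def test_log_transform_equal_steps_and_errors(self, tiny_graph, rng):
        n = 9
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        vals = np.array([10.0, 100.0, 1000.0] * 3)
        res = clinical_association(
            Y, vals, graph=tiny_graph, n_perm=20, seed=0
        )
        assert res.n_perm >= 19
        with pytest.raises(ValueError, match="positive"):
            clinical_association(Y, np.zeros(n), graph=tiny_graph, n_perm=20)

    def test_null_clinical_association_uncalibrated_low_fp(self, tiny_graph, rng):
        n = 18
        Y = rng.normal(size=(n, tiny_graph.n_vertices))
        vals = rng.lognormal(3, 1, size=n)
        res = clinical_association(Y, vals, graph=tiny_graph, n_perm=99, seed=1)
        assert res.p_fwe.min() > 0.01
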