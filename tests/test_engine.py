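import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prostasm as pa
from prostasm.appearance import VertexAppearance, _pca_profiles
from prostasm.engine import PRESETS, movement_from_profile


def _toy_appearance():
    """Hand-built appearance statistics with two known eigen-modes."""
    g_mean = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    w1 = np.array([1.0, 0, 0, 0, 0])
    w2 = np.array([0, 1.0, 0, 0, 0])
    return VertexAppearance(
        g_mean=g_mean, Wg=np.stack([w1, w2], axis=1), eigenvalues=np.array([4.0, 2.0])
    )


class TestProfileCost:
    def test_zero_at_mean(self):
        m = _toy_appearance()
        assert pa.profile_cost(m.g_mean, m) == 0.0

    def test_unit_cost_at_one_eigenvalue_along_leading_mode(self):
        m = _toy_appearance()
        g = m.g_mean + m.eigenvalues[0] * m.Wg[:, 0]
        assert pa.profile_cost(g, m) == pytest.approx(1.0)

    def test_invariant_to_out_of_span_deviation(self):
        m = _toy_appearance()
        off_span = np.array([0, 0, 5.0, -3.0, 7.0])  # orthogonal to w1, w2
        g = m.g_mean + 2.0 * m.Wg[:, 0]
        assert pa.profile_cost(g + off_span, m) == pytest.approx(pa.profile_cost(g, m))

    def test_sqrt_scaling_option(self):
        m = _toy_appearance()
        g = m.g_mean + np.sqrt(m.eigenvalues[0]) * m.Wg[:, 0]
        assert pa.profile_cost(g, m, eigen_scaling="sqrt") == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pa.profile_cost(np.zeros(7), _toy_appearance())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=5))
    def test_nonnegative_quadratic_form(self, g):
        assert pa.profile_cost(np.array(g), _toy_appearance()) >= 0.0


class TestBestMovement:
    def test_index_arithmetic_extremes(self):
        m = _toy_appearance()
        # force the minimum at the first candidate: cost decreasing with index
        ns = 8
        extended = np.linspace(0, 1, 2 * (ns + 2) + 1) * 1e3
        extended[0:5] = m.g_mean  # ind = 1 (movement -8) matches the mean
        assert movement_from_profile(extended, m, ns, 2) == -8

    def test_center_candidate_movement_zero(self):
        m = _toy_appearance()
        ns = 8
        extended = np.full(2 * (ns + 2) + 1, 1e4)
        extended[ns : ns + 5] = m.g_mean  # centred sub-profile
        assert movement_from_profile(extended, m, ns, 2) == 0

    def test_tie_breaks_prefer_staying(self):
        m = _toy_appearance()
        ns = 4
        extended = np.zeros(2 * (ns + 2) + 1)  # constant: every candidate ties
        assert movement_from_profile(extended, m, ns, 2) == 0

    def test_movement_bounded(self):
        rng = np.random.default_rng(0)
        m = _toy_appearance()
        for _ in range(10):
            ns = int(rng.integers(2, 9))
            ext = rng.random(2 * (ns + 2) + 1) * 100
            assert abs(movement_from_profile(ext, m, ns, 2)) <= ns

    def test_planted_edge_displacement_recovered(self):
        """Appearance model trained on noisy centred edges finds a boundary
        displaced by a known number of samples."""
        x0 = 20.0
        xs = np.arange(80) * 0.5
        data = np.tile(
            (100.0 / (1 + np.exp(-(xs - x0) / 1.0)))[:, None, None], (1, 40, 40)
        )
        vol = pa.Volume(data, (0.5, 0.5, 0.5))

        def edge(d):
            k = np.arange(-2, 3) * 0.5
            return 100.0 / (1 + np.exp(-(k + d) / 1.0))

        rng = np.random.default_rng(0)
        model = _pca_profiles(np.stack([edge(0.0) + rng.normal(0, 1.0, 5) for _ in range(10)]))
        normal = np.array([1.0, 0, 0])
        for disp_mm, expect in [(-1.5, 3), (0.0, 0), (2.0, -4), (1.0, -2)]:
            pt = np.array([x0 + disp_mm, 10.0, 10.0])
            assert pa.best_movement(vol, pt, normal, model, 8) == expect

    def test_search_shorter_than_model_rejected(self):
        vol = pa.Volume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError):
            pa.best_movement(vol, (2, 2, 2), (1.0, 0, 0), _toy_appearance(), ns_search=1)


def _toy_shape_model():
    rng = np.random.default_rng(1)
    K = 30
    x_mean = rng.random(3 * K) * 40
    basis = np.linalg.qr(rng.normal(size=(3 * K, 3)))[0]
    eig = np.array([9.0, 4.0, 1.0])
    return pa.ShapeModel(
        x_mean=x_mean, Ws=basis, eigenvalues=eig, variance_retained=0.99, total_variance=eig.sum()
    )


class TestConstrainShape:
    def test_mean_maps_to_mean(self):
        sm = _toy_shape_model()
        out, bv = pa.constrain_shape(pa.CorrespondedShape.from_vector(sm.x_mean), sm, 2.0)
        np.testing.assert_allclose(out.as_vector(), sm.x_mean, atol=1e-9)
        np.testing.assert_allclose(bv.b, 0.0, atol=1e-9)

    def test_within_bounds_shape_unchanged(self):
        sm = _toy_shape_model()
        x = sm.x_mean + 0.5 * 2.0 * sm.eigenvalues[0] * sm.Ws[:, 0]
        out, bv = pa.constrain_shape(pa.CorrespondedShape.from_vector(x), sm, 2.0)
        np.testing.assert_allclose(out.as_vector(), x, atol=1e-9)
        assert not bv.clamped.any()

    def test_out_of_bounds_mode_clamped(self):
        sm = _toy_shape_model()
        x = sm.x_mean + 2.0 * 2.0 * sm.eigenvalues[0] * sm.Ws[:, 0]
        out, bv = pa.constrain_shape(pa.CorrespondedShape.from_vector(x), sm, 2.0)
        assert bv.clamped[0] and bv.n_clamped == 1
        assert bv.b[0] == pytest.approx(2.0 * sm.eigenvalues[0])

    def test_zero_constraint_collapses_to_mean(self):
        sm = _toy_shape_model()
        rng = np.random.default_rng(2)
        x = sm.x_mean + rng.normal(0, 50, sm.x_mean.size)
        out, _ = pa.constrain_shape(pa.CorrespondedShape.from_vector(x), sm, 0.0)
        np.testing.assert_allclose(out.as_vector(), sm.x_mean, atol=1e-9)

    def test_idempotence(self):
        sm = _toy_shape_model()
        rng = np.random.default_rng(3)
        x = sm.x_mean + rng.normal(0, 30, sm.x_mean.size)
        once, b1 = pa.constrain_shape(pa.CorrespondedShape.from_vector(x), sm, 1.5)
        twice, b2 = pa.constrain_shape(once, sm, 1.5)
        np.testing.assert_allclose(twice.as_vector(), once.as_vector(), atol=1e-9)
        np.testing.assert_allclose(b1.b, b2.b, atol=1e-9)

    def test_out_of_span_residual_discarded(self):
        sm = _toy_shape_model()
        rng = np.random.default_rng(4)
        resid = rng.normal(size=sm.x_mean.size)
        resid -= sm.Ws @ (sm.Ws.T @ resid)
        x = sm.x_mean + resid
        out, bv = pa.constrain_shape(pa.CorrespondedShape.from_vector(x), sm, 2.0)
        np.testing.assert_allclose(out.as_vector(), sm.x_mean, atol=1e-9)

    def test_vertex_count_mismatch(self):
        sm = _toy_shape_model()
        with pytest.raises(ValueError):
            pa.constrain_shape(pa.CorrespondedShape(np.zeros((5, 3))), sm, 1.0)


class TestASMConfig:
    def test_presets_match_evaluated_configurations(self):
        assert PRESETS["ASM-1"] == pa.ASMConfig(iterations=1, ns_search=8, m=3.0)
        assert PRESETS["ASM-2"] == pa.ASMConfig(iterations=2, ns_search=8, m=1.0)
        assert PRESETS["ASM-3"] == pa.ASMConfig(iterations=2, ns_search=8, m=2.0)
        assert PRESETS["ASM-4"] == pa.ASMConfig(iterations=2, ns_search=8, m=3.0)

    def test_default_is_reported_best_setting(self):
        assert pa.DEFAULT_CONFIG == pa.ASMConfig(iterations=2, ns_search=8, m=2.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"iterations": -1},
            {"ns_search": 1},
            {"m": -0.5},
            {"eigen_scaling": "log"},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pa.ASMConfig(**kwargs)


class TestRefine:
    def test_zero_iterations_is_identity(self, default_cohort, trained_archive):
        vol, mask, _ = default_cohort[9]
        iso_vol = pa.resample_isotropic(vol, 0.5)
        iso_mask = pa.resample_isotropic(mask, 0.5, mode="nearest")
        init = pa.extract_corresponded_vertices(iso_mask, trained_archive.ray_config)
        out = pa.refine(
            iso_vol,
            init,
            trained_archive.shape_model,
            trained_archive.appearance_model,
            pa.ASMConfig(iterations=0),
        )
        np.testing.assert_array_equal(out.vertices, init.vertices)

    def test_truth_initialisation_is_stable(self, default_cohort, trained_archive):
        """Starting from the reference shape, refinement stays close to it."""
        vol, mask, _ = default_cohort[10]
        iso_vol = pa.resample_isotropic(vol, 0.5)
        iso_mask = pa.resample_isotropic(mask, 0.5, mode="nearest")
        init = pa.extract_corresponded_vertices(iso_mask, trained_archive.ray_config)
        out = pa.refine(
            iso_vol,
            init,
            trained_archive.shape_model,
            trained_archive.appearance_model,
            pa.DEFAULT_CONFIG,
        )
        mean_dist = np.linalg.norm(out.vertices - init.vertices, axis=1).mean()
        assert mean_dist < 1.5

    def test_vertex_count_mismatch_rejected(self, trained_archive):
        vol = pa.Volume(np.ones((8, 8, 8)))
        bad = pa.CorrespondedShape(np.zeros((7, 3)))
        with pytest.raises(ValueError):
            pa.refine(
                vol,
                bad,
                trained_archive.shape_model,
                trained_archive.appearance_model,
                pa.DEFAULT_CONFIG,
            )
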