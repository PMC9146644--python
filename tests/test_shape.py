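import numpy as np
import pytest

import prostasm as pa
from prostasm.shape import (
    CorrespondenceError,
    FitError,
    Ray,
    RayConfig,
    TopologyError,
    _rotate_pair,
    mask_surface_points,
)


def _ellipsoid_mask(radii, spacing=(1.0, 1.0, 1.0), pad=6):
    shape = tuple(int(2 * (r / s + pad)) for r, s in zip(radii, spacing))
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    center = [(n - 1) / 2 * s for n, s in zip(shape, spacing)]
    rho = sum(
        ((g * s - c) / r) ** 2 for g, s, c, r in zip(grids, spacing, center, radii)
    )
    return pa.BinaryMask(rho <= 1.0, spacing)


class TestFitEllipsoid:
    def test_recovers_axis_aligned_radii(self):
        mask = _ellipsoid_mask((30, 20, 20))
        fit = pa.fit_ellipsoid(mask)
        center = np.array([(s - 1) / 2 for s in mask.shape])
        assert np.abs(fit.center - center).max() < 1.0
        np.testing.assert_allclose(fit.axis_radii, (30, 20, 20), rtol=0.05)

    def test_sphere_degenerate_focal_distance(self, sphere_mask_iso):
        fit = pa.fit_ellipsoid(sphere_mask_iso)
        assert fit.radii[0] == pytest.approx(fit.radii[-1], rel=0.03)
        # c_xy ~ 0 for a sphere: the F_xy pair collapses onto the centre
        assert np.linalg.norm(fit.f_xy[0] - fit.f_xy[1]) < 2.0
        # key points differ only along the documented axes
        np.testing.assert_allclose(fit.f_xy[0][[0, 2]], fit.center[[0, 2]], atol=1e-9)
        np.testing.assert_allclose(fit.f_xz[0][[1, 2]], fit.center[[1, 2]], atol=1e-9)

    def test_single_voxel_rejected(self):
        m = np.zeros((8, 8, 8))
        m[4, 4, 4] = 1
        with pytest.raises(FitError):
            pa.fit_ellipsoid(pa.BinaryMask(m))

    def test_key_points_inside_bounding_box(self):
        mask = _ellipsoid_mask((25, 20, 15))
        fit = pa.fit_ellipsoid(mask)
        idx = np.argwhere(mask.data)
        lo = idx.min(axis=0).astype(float)
        hi = idx.max(axis=0).astype(float)
        for kp in fit.key_points:
            assert np.all(kp > lo) and np.all(kp < hi)


def _sphere_points(n, r=20.0, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return r * d


class TestAlphaTriangulate:
    def test_sphere_surface_area(self):
        pts = _sphere_points(2000, r=20.0)
        mesh = pa.alpha_triangulate(pts, alpha=50.0)
        assert abs(mesh.area() - 4 * np.pi * 20.0**2) / (4 * np.pi * 20.0**2) < 0.10
        assert mesh.is_closed()

    def test_watertight_against_trimesh(self):
        trimesh = pytest.importorskip("trimesh")
        pts = _sphere_points(800, r=10.0, seed=1)
        mesh = pa.alpha_triangulate(pts, alpha=30.0)
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
        assert tm.is_watertight
        assert tm.euler_number == 2

    def test_tetrahedron_convex_hull_limit(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mesh = pa.alpha_triangulate(pts, alpha=100.0)
        assert len(mesh.triangles) == 4
        assert mesh.is_closed()

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            pa.alpha_triangulate(pts, alpha=10.0)

    def test_alpha_too_small_names_components(self):
        pts = _sphere_points(500, r=20.0, seed=2)
        with pytest.raises(TopologyError):
            pa.alpha_triangulate(pts, alpha=0.5)


class TestRayTriangleIntersect:
    def test_hand_computed_hit(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ray = Ray(origin=(0.25, 0.25, -1.0), direction=(0, 0, 1))
        t, u, v = pa.ray_triangle_intersect(ray, tri)
        assert (t, u, v) == pytest.approx((1.0, 0.25, 0.25))

    def test_parallel_offset_ray_misses(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ray = Ray(origin=(0, 0, 1.0), direction=(1, 0, 0))
        assert pa.ray_triangle_intersect(ray, tri) is None

    def test_point_outside_triangle_misses(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ray = Ray(origin=(0.8, 0.8, -1.0), direction=(0, 0, 1))
        assert pa.ray_triangle_intersect(ray, tri) is None

    def test_back_face_hit_allowed(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ray = Ray(origin=(0.25, 0.25, 1.0), direction=(0, 0, -1))
        t, _, _ = pa.ray_triangle_intersect(ray, tri)
        assert t == pytest.approx(1.0)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            Ray(origin=(0, 0, 0), direction=(0, 0, 0))

    def test_degenerate_triangle_rejected(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            pa.ray_triangle_intersect(Ray((0, 0, -1), (0, 0, 1)), tri)


class TestCorrespondence:
    def test_sphere_center_rays_at_radius(self, sphere_mask_iso):
        shape = pa.extract_corresponded_vertices(sphere_mask_iso)
        fit = pa.fit_ellipsoid(sphere_mask_iso)
        d = np.linalg.norm(shape.vertices[:56] - fit.center, axis=1)
        assert np.abs(d - 20.0).max() < 1.0  # within ~1 working voxel of r

    def test_deterministic(self, sphere_mask_iso):
        s1 = pa.extract_corresponded_vertices(sphere_mask_iso)
        s2 = pa.extract_corresponded_vertices(sphere_mask_iso)
        np.testing.assert_array_equal(s1.vertices, s2.vertices)

    def test_fixed_cardinality(self, sphere_mask_iso):
        cfg = RayConfig()
        shape = pa.extract_corresponded_vertices(sphere_mask_iso, cfg)
        assert shape.K == cfg.K == 5 * 8 * 7

    def test_detached_blob_captures_rays(self):
        """Documented hazard: a detached blob near the gland merges into the
        alpha shape and farthest-hit rays land on it; cleanup removes it."""
        from prostasm.postprocess import clean_mask

        m = _ellipsoid_mask((15, 15, 15), spacing=(1, 1, 1), pad=22)
        center_idx = np.array(m.shape) // 2
        grids = np.meshgrid(*[np.arange(s) for s in m.shape], indexing="ij")
        blob = (
            sum((g - c) ** 2 for g, c in zip(grids, center_idx + np.array([26, 0, 0])))
            <= 5.0**2
        )
        two = pa.BinaryMask(m.data.astype(bool) | blob, m.spacing)
        shape_with_blob = pa.extract_corresponded_vertices(two)
        shape_clean = pa.extract_corresponded_vertices(clean_mask(two))
        fit = pa.fit_ellipsoid(clean_mask(two))
        far_with = np.linalg.norm(shape_with_blob.vertices - fit.center, axis=1).max()
        far_clean = np.linalg.norm(shape_clean.vertices - fit.center, axis=1).max()
        assert far_with > 22.0  # some vertex well beyond the 15 mm gland
        assert far_clean < 20.0


class TestAlignShape:
    def _shape(self, seed=0):
        return pa.CorrespondedShape(_sphere_points(60, r=15.0, seed=seed) * [1.3, 1.0, 0.8])

    def test_self_alignment_is_identity(self):
        s = self._shape()
        aligned, tr = pa.align_shape(s, s)
        np.testing.assert_allclose(aligned.vertices, s.vertices, atol=1e-9)
        assert tr.rot_xy == pytest.approx(0.0, abs=1e-9)
        assert tr.rot_xz == pytest.approx(0.0, abs=1e-9)

    def test_translation_recovered_exactly(self):
        s = self._shape()
        moved = pa.CorrespondedShape(s.vertices + [5.0, -3.0, 2.0])
        aligned, tr = pa.align_shape(moved, s)
        np.testing.assert_allclose(tr.translation, [-5.0, 3.0, -2.0], atol=1e-9)
        assert abs(tr.rot_xy) < 1e-9 and abs(tr.rot_xz) < 1e-9
        np.testing.assert_allclose(aligned.vertices, s.vertices, atol=1e-9)

    def test_z_rotation_recovered(self):
        s = self._shape(seed=3)
        theta = np.deg2rad(20.0)
        rotated = pa.CorrespondedShape(_rotate_pair(s.vertices, 0, 1, theta))
        aligned, tr = pa.align_shape(rotated, s)
        assert tr.rot_xy == pytest.approx(-theta, abs=1e-6)
        rms = np.sqrt(((aligned.vertices - s.vertices) ** 2).sum(axis=1).mean())
        assert rms < 0.1

    def test_round_trip_inversion(self):
        s = self._shape(seed=5)
        ref = self._shape(seed=6)
        aligned, tr = pa.align_shape(s, ref)
        back = tr.invert(aligned.vertices)
        np.testing.assert_allclose(back, s.vertices, atol=1e-6)

    def test_vertex_count_mismatch(self):
        with pytest.raises(ValueError):
            pa.align_shape(
                pa.CorrespondedShape(np.zeros((5, 3))),
                pa.CorrespondedShape(np.zeros((6, 3))),
            )


class TestBuildShapeModel:
    def test_identical_shapes_have_no_modes(self):
        s = pa.CorrespondedShape(_sphere_points(40, seed=1))
        model = pa.build_shape_model([s, s, s])
        assert model.n_modes == 0
        np.testing.assert_allclose(model.x_mean, s.as_vector())

    def test_rank_bound(self):
        rng = np.random.default_rng(2)
        shapes = [
            pa.CorrespondedShape(_sphere_points(40, seed=3) + rng.normal(0, 0.5, (40, 3)))
            for _ in range(5)
        ]
        model = pa.build_shape_model(shapes, variance=1.0)
        assert model.n_modes <= len(shapes) - 1

    def test_training_shape_reconstruction(self):
        rng = np.random.default_rng(4)
        base = _sphere_points(40, seed=7)
        shapes = [
            pa.CorrespondedShape(base + rng.normal(0, 1.0, (40, 3))) for _ in range(6)
        ]
        model = pa.build_shape_model(shapes, variance=1.0)
        x = shapes[2].as_vector()
        b = model.Ws.T @ (x - model.x_mean)
        recon = model.x_mean + model.Ws @ b
        rms = np.sqrt(((recon - x) ** 2).mean())
        assert rms < 1e-6

    def test_retained_variance_threshold(self):
        rng = np.random.default_rng(6)
        base = _sphere_points(40, seed=8)
        d = rng.normal(size=120)
        shapes = [
            pa.CorrespondedShape(
                (base.reshape(-1) + t * d + rng.normal(0, 0.01, 120)).reshape(-1, 3)
            )
            for t in rng.normal(0, 2.0, 8)
        ]
        model = pa.build_shape_model(shapes, variance=0.98)
        assert model.variance_retained >= 0.98
        assert model.eigenvalues[0] > 100 * model.eigenvalues[-1] or model.n_modes == 1

    def test_too_few_shapes_rejected(self):
        s = pa.CorrespondedShape(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            pa.build_shape_model([s, s])


def test_surface_points_subvoxel_smoothness(sphere_mask_iso):
    """Marching-cubes surface points deviate from the true sphere by well
    under a voxel on average."""
    pts = mask_surface_points(sphere_mask_iso)
    center = pts.mean(axis=0)
    r = np.linalg.norm(pts - center, axis=1)
    assert abs(r.mean() - 20.0) < 0.5
    assert r.std() < 0.5
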