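"""Point distribution model construction.

Corresponded surface vertices are extracted from every training mask with the
same deterministic recipe, so that vertex *k* means the same anatomical spot
on every subject:

1. fit an axis-aligned ellipsoid to the mask surface and derive interior key
   points from its focal geometry;
2. triangulate the surface points with a 3D alpha shape;
3. cast a fixed fan of rays from the key points and keep, per ray, the
   farthest ray-triangle intersection (Moller-Trumbore);
4. stack the hit points in (source, direction)-lexicographic order.

Shapes are then rigidly aligned (translation plus two four-quadrant-arctangent
rotation steps) and a PCA retaining 98% of total variance yields the mean
shape and its modes of variation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

from .volume import BinaryMask

_CROSS6 = ndimage.generate_binary_structure(3, 1)


class FitError(ValueError):
    """Ellipsoid fitting failed (degenerate or insufficient surface)."""


class TopologyError(ValueError):
    """The alpha shape is not a single closed surface."""


class CorrespondenceError(ValueError):
    """A correspondence ray failed to intersect the surface mesh."""


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass(frozen=True)
class EllipsoidFit:
    """Axis-aligned least-squares ellipsoid with derived key points.

    The in-plane focal distance ``c_xy = sqrt(radius_max^2 - radius_min^2)``
    and ``c_xz = radius_min`` place four interior reference points::

        F_xy± = (xc, yc ± c_xy/2, zc)      F_xz± = (xc ± c_xz/2, yc, zc)
    """

    center: np.ndarray
    radii: np.ndarray  # sorted descending: radius_max >= .. >= radius_min
    axis_radii: np.ndarray  # (rx, ry, rz) in axis order
    f_xy: tuple[np.ndarray, np.ndarray]  # (+, -) pair, differing in y
    f_xz: tuple[np.ndarray, np.ndarray]  # (+, -) pair, differing in x

    @property
    def key_points(self) -> np.ndarray:
        """(5, 3) array: center, F_xy+, F_xy-, F_xz+, F_xz-."""
        return np.stack([self.center, *self.f_xy, *self.f_xz])


@dataclasses.dataclass(frozen=True)
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (T, 3) vertex indices

    def triangle_coords(self) -> np.ndarray:
        return self.vertices[self.triangles]  # (T, 3, 3)

    def area(self) -> float:
        tc = self.triangle_coords()
        cross = np.cross(tc[:, 1] - tc[:, 0], tc[:, 2] - tc[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def edge_counts(self) -> dict:
        counts: dict = {}
        for tri in self.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def is_closed(self) -> bool:
        return all(c == 2 for c in self.edge_counts().values())


@dataclasses.dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", d / n)


@dataclasses.dataclass(frozen=True)
class CorrespondedShape:
    """Fixed-length, consistently ordered surface vertex list (K, 3) in mm."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (K, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite vertex coordinates")
        object.__setattr__(self, "vertices", v)

    @property
    def K(self) -> int:
        return self.vertices.shape[0]

    def as_vector(self) -> np.ndarray:
        return self.vertices.reshape(-1)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "CorrespondedShape":
        return cls(np.asarray(x, dtype=float).reshape(-1, 3))

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclasses.dataclass(frozen=True)
class ShapeModel:
    """PCA shape model: mean, eigenvectors Ws, eigenvalues lambda_s."""

    x_mean: np.ndarray  # (3K,)
    Ws: np.ndarray  # (3K, t), orthonormal columns
    eigenvalues: np.ndarray  # (t,), descending
    variance_retained: float
    total_variance: float

    @property
    def K(self) -> int:
        return self.x_mean.size // 3

    @property
    def n_modes(self) -> int:
        return self.Ws.shape[1]

    @property
    def mean_shape(self) -> CorrespondedShape:
        return CorrespondedShape.from_vector(self.x_mean)


@dataclasses.dataclass(frozen=True)
class AlignmentTransform:
    """Rigid alignment: centroid shift plus two in-plane rotations.

    Stored so the exact inverse can be applied after model-space operations:
    ``aligned = R_xz(rot_xz) @ R_xy(rot_xy) @ (x - centroid) + ref_centroid``
    where R_xy rotates the (x, y) coordinate pair and R_xz the (x, z) pair.
    """

    centroid: np.ndarray
    ref_centroid: np.ndarray
    rot_xy: float  # radians, rotation applied in the x-y plane (about z)
    rot_xz: float  # radians, rotation applied in the x-z plane (about y)

    @property
    def translation(self) -> np.ndarray:
        return self.ref_centroid - self.centroid

    def apply(self, vertices: np.ndarray) -> np.ndarray:
        p = np.asarray(vertices, dtype=float) - self.centroid
        p = _rotate_pair(p, 0, 1, self.rot_xy)
        p = _rotate_pair(p, 0, 2, self.rot_xz)
        return p + self.ref_centroid

    def invert(self, vertices: np.ndarray) -> np.ndarray:
        p = np.asarray(vertices, dtype=float) - self.ref_centroid
        p = _rotate_pair(p, 0, 2, -self.rot_xz)
        p = _rotate_pair(p, 0, 1, -self.rot_xy)
        return p + self.centroid


@dataclasses.dataclass(frozen=True)
class RayConfig:
    """Fan of correspondence rays shared by every shape of one model.

    8 azimuths at a 45 degree step, times ``elevations_deg`` elevation rings,
    cast from each of the 5 ellipsoid key points: K = 5 * 8 * 7 = 280 with
    the defaults.  The fan stops at +-45 degrees: steeper rays meet the
    gland near its apex/base where the surface runs almost parallel to the
    thick acquisition slices, and vertex positions there are dominated by
    slice quantization rather than anatomy.
    """

    n_azimuths: int = 8
    elevations_deg: tuple[float, ...] = (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0)
    alpha: float = 50.0
    max_surface_points: int = 3000

    @property
    def n_sources(self) -> int:
        return 5

    @property
    def K(self) -> int:
        return self.n_sources * self.n_azimuths * len(self.elevations_deg)

    def directions(self) -> np.ndarray:
        """(n_dirs, 3) unit vectors, elevation-major then azimuth order."""
        azimuths = np.arange(self.n_azimuths) * (2 * np.pi / self.n_azimuths)
        dirs = []
        for el_deg in self.elevations_deg:
            el = np.deg2rad(el_deg)
            for az in azimuths:
                dirs.append(
                    (np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el))
                )
        return np.asarray(dirs)


# ---------------------------------------------------------------------------
# surface extraction and ellipsoid fit


def mask_surface_points(mask: BinaryMask, smooth_sigma_mm: float = 2.5) -> np.ndarray:
    """Sub-voxel surface points (mm) of a binary mask.

    The mask is Gaussian-smoothed (sigma in mm, converted per axis to
    voxels) and its 0.5 level set extracted with marching cubes.  The
    smoothing scale is set by the acquisition: masks inherit a staircase
    from the thick slices of the native grid (3 mm in the modeled protocol)
    that survives nearest-neighbour isotropic upsampling, and that jitter
    would otherwise dominate the small eigenvalues of the shape PCA.  Falls
    back to 6-connectivity surface voxel centres for masks too small to
    contour.
    """
    fg = mask.data.astype(float)
    if smooth_sigma_mm > 0:
        sigma_vox = [smooth_sigma_mm / s for s in mask.spacing]
        field = ndimage.gaussian_filter(fg, sigma_vox)
    else:
        field = fg
    try:
        from skimage.measure import marching_cubes

        verts, _faces, _n, _v = marching_cubes(field, level=0.5, spacing=mask.spacing)
        if len(verts) >= 10:
            return verts + np.asarray(mask.origin)
    except (ValueError, RuntimeError):
        pass
    surf = mask.data.astype(bool) & ~ndimage.binary_erosion(
        mask.data.astype(bool), structure=_CROSS6, border_value=0
    )
    return mask.index_to_physical(np.argwhere(surf))


def fit_ellipsoid(mask: BinaryMask) -> EllipsoidFit:
    """Axis-aligned algebraic least-squares ellipsoid through surface voxels.

    Solves ``A x^2 + B y^2 + C z^2 + D x + E y + F z = 1`` and requires all
    quadratic coefficients positive (a real ellipsoid).
    """
    pts = mask_surface_points(mask)
    if pts.shape[0] < 10:
        raise FitError(f"need >= 10 surface voxels, got {pts.shape[0]}")
    x, y, z = pts.T
    design = np.column_stack([x * x, y * y, z * z, x, y, z])
    coef, *_ = np.linalg.lstsq(design, np.ones(len(pts)), rcond=None)
    A, B, C, D, E, F = coef
    # an ellipsoid requires all three quadratic coefficients of one sign
    # (the common sign flips when the centre lies far from the origin)
    if A == 0 or B == 0 or C == 0 or not (np.sign(A) == np.sign(B) == np.sign(C)):
        raise FitError("surface points do not determine an ellipsoid")
    center = np.array([-D / (2 * A), -E / (2 * B), -F / (2 * C)])
    g = 1.0 + A * center[0] ** 2 + B * center[1] ** 2 + C * center[2] ** 2
    ratios = g / np.array([A, B, C])
    if np.any(ratios <= 0):
        raise FitError("degenerate quadric (non-ellipsoidal gauge)")
    axis_radii = np.sqrt(ratios)
    radii = np.sort(axis_radii)[::-1]
    r_max, r_min = radii[0], radii[-1]
    c_xy = float(np.sqrt(max(r_max**2 - r_min**2, 0.0)))
    c_xz = float(r_min)
    f_xy = (
        center + np.array([0.0, +c_xy / 2, 0.0]),
        center + np.array([0.0, -c_xy / 2, 0.0]),
    )
    f_xz = (
        center + np.array([+c_xz / 2, 0.0, 0.0]),
        center + np.array([-c_xz / 2, 0.0, 0.0]),
    )
    return EllipsoidFit(center=center, radii=radii, axis_radii=axis_radii, f_xy=f_xy, f_xz=f_xz)


# ---------------------------------------------------------------------------
# alpha-shape triangulation


def _tet_circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized)."""
    p = points[tets]  # (n, 4, 3)
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    M = np.stack([a, b, c], axis=1)  # rows are edge vectors
    rhs = 0.5 * np.stack(
        [(a * a).sum(1), (b * b).sum(1), (c * c).sum(1)], axis=1
    )
    det = np.linalg.det(M)
    radii = np.full(len(tets), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def alpha_triangulate(points: np.ndarray, alpha: float) -> SurfaceMesh:
    """3D alpha-shape surface of a point cloud.

    Delaunay tetrahedralization restricted to tetrahedra with circumradius
    below ``alpha`` (mm); the surface is the set of faces belonging to exactly
    one kept tetrahedron.  Raises :class:`TopologyError` if the result is not
    one closed component.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 4:
        raise ValueError("need at least 4 points in 3D")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull raises on coplanar input
        raise ValueError(f"triangulation failed (coplanar/degenerate points?): {exc}")
    radii = _tet_circumradii(points, tri.simplices)
    kept = tri.simplices[radii < alpha]
    if len(kept) == 0:
        raise TopologyError("alpha too small: no tetrahedra retained (0 components)")

    faces = np.concatenate(
        [kept[:, [0, 1, 2]], kept[:, [0, 1, 3]], kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]
    )
    faces_sorted = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces_sorted, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        raise TopologyError("alpha shape has no boundary faces")

    # drop degenerate (zero-area) triangles
    tc = points[boundary]
    areas = 0.5 * np.linalg.norm(
        np.cross(tc[:, 1] - tc[:, 0], tc[:, 2] - tc[:, 0]), axis=1
    )
    boundary = boundary[areas > 1e-12]
    areas = areas[areas > 1e-12]

    # removing sliver tetrahedra can open tiny interior cavities whose
    # boundaries count as extra (closed) components; discard those, but treat
    # genuine fragmentation of the outer surface as a topology error
    labels = _face_component_labels(boundary)
    comp_area = np.zeros(labels.max() + 1)
    np.add.at(comp_area, labels, areas)
    main = int(np.argmax(comp_area))
    significant = int(np.sum(comp_area > 0.1 * comp_area[main]))
    if significant != 1:
        raise TopologyError(
            f"alpha shape has {significant} major surface components; increase alpha"
        )
    boundary = boundary[labels == main]

    used = np.unique(boundary)
    remap = -np.ones(points.shape[0], dtype=int)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(vertices=points[used], triangles=remap[boundary])


def _face_component_labels(faces: np.ndarray) -> np.ndarray:
    """Connected-component label per face (shared-vertex connectivity)."""
    parent: dict = {}

    def find(a):
        while parent.setdefault(a, a) != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for f in faces:
        union(int(f[0]), int(f[1]))
        union(int(f[0]), int(f[2]))
    roots = {}
    labels = np.empty(len(faces), dtype=int)
    for i, f in enumerate(faces):
        r = find(int(f[0]))
        labels[i] = roots.setdefault(r, len(roots))
    return labels


# ---------------------------------------------------------------------------
# ray-triangle intersection (Moller-Trumbore)

_MT_EPS = 1e-12
_MT_EDGE_TOL = 1e-9


def ray_triangle_intersect(ray: Ray, tri: np.ndarray):
    """Moller-Trumbore intersection of one ray with one triangle.

    Returns ``(t, u, v)`` with barycentric ``u, v >= 0``, ``u + v <= 1`` and
    ray parameter ``t >= 0`` for a front- or back-face hit, else ``None``.
    """
    tri = np.asarray(tri, dtype=float)
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    if np.linalg.norm(np.cross(e1, e2)) < _MT_EPS:
        raise ValueError("degenerate triangle")
    pvec = np.cross(ray.direction, e2)
    det = e1 @ pvec
    if abs(det) < _MT_EPS:
        return None
    inv_det = 1.0 / det
    tvec = ray.origin - tri[0]
    u = (tvec @ pvec) * inv_det
    if u < -_MT_EDGE_TOL or u > 1.0 + _MT_EDGE_TOL:
        return None
    qvec = np.cross(tvec, e1)
    v = (ray.direction @ qvec) * inv_det
    if v < -_MT_EDGE_TOL or u + v > 1.0 + _MT_EDGE_TOL:
        return None
    t = (e2 @ qvec) * inv_det
    if t < -_MT_EDGE_TOL:
        return None
    return float(t), float(u), float(v)


def _ray_mesh_max_t(origin: np.ndarray, direction: np.ndarray, tri_coords: np.ndarray):
    """Largest ray parameter t over all hit triangles, or None (vectorized)."""
    v0 = tri_coords[:, 0]
    e1 = tri_coords[:, 1] - v0
    e2 = tri_coords[:, 2] - v0
    pvec = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _MT_EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin[None, :] - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = qvec @ direction * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = (
        ok
        & (u >= -_MT_EDGE_TOL)
        & (v >= -_MT_EDGE_TOL)
        & (u + v <= 1.0 + _MT_EDGE_TOL)
        & (t >= -_MT_EDGE_TOL)
    )
    if not hit.any():
        return None
    return float(t[hit].max())


# ---------------------------------------------------------------------------
# corresponded vertices


def _subsample_points(points: np.ndarray, max_points: int) -> np.ndarray:
    """Deterministic even-stride subsample after lexicographic sort."""
    if len(points) <= max_points:
        return points
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    idx = np.linspace(0, len(points) - 1, max_points).round().astype(int)
    return points[order][idx]


def extract_corresponded_vertices(
    mask: BinaryMask,
    ray_config: RayConfig | None = None,
    return_mesh: bool = False,
):
    """Deterministic fixed-size corresponded vertex list for one mask.

    For each of the 5 ellipsoid key points and each configured direction the
    farthest intersection with the alpha-shape surface is recorded (larger t
    wins ties), in (source, direction)-lexicographic order.  The mask should
    be on an isotropic grid (0.5 mm in the standard pipeline).

    With ``return_mesh=True`` the dense alpha-shape surface the rays were
    cast against is returned as well — useful for normal estimation, which
    is far more accurate on this mesh than on the sparse vertex polyhedron.
    """
    cfg = ray_config if ray_config is not None else RayConfig()
    pts = mask_surface_points(mask)
    if len(pts) < 4:
        raise FitError("mask surface too small for correspondence")
    pts = _subsample_points(pts, cfg.max_surface_points)
    mesh = alpha_triangulate(pts, cfg.alpha)
    fit = fit_ellipsoid(mask)
    tri_coords = mesh.triangle_coords()
    dirs = cfg.directions()
    vertices = np.empty((cfg.K, 3))
    k = 0
    for s, source in enumerate(fit.key_points):
        for d, direction in enumerate(dirs):
            t = _ray_mesh_max_t(source, direction, tri_coords)
            if t is None:
                raise CorrespondenceError(
                    f"ray (source {s}, direction {d}) missed the surface mesh"
                )
            vertices[k] = source + t * direction
            k += 1
    shape = CorrespondedShape(vertices)
    return (shape, mesh) if return_mesh else shape


# ---------------------------------------------------------------------------
# alignment


def _rotate_pair(p: np.ndarray, i: int, j: int, angle: float) -> np.ndarray:
    out = p.copy()
    c, s = np.cos(angle), np.sin(angle)
    out[:, i] = c * p[:, i] - s * p[:, j]
    out[:, j] = s * p[:, i] + c * p[:, j]
    return out


def _procrustes_angle(p2: np.ndarray, r2: np.ndarray) -> float:
    """Planar rotation of corresponded centred points p2 onto r2.

    Closed form via the four-quadrant inverse tangent:
    ``atan2(sum(p x r), sum(p . r))`` minimises the in-plane squared
    distance over rotations.
    """
    cross = p2[:, 0] * r2[:, 1] - p2[:, 1] * r2[:, 0]
    dot = p2[:, 0] * r2[:, 0] + p2[:, 1] * r2[:, 1]
    return float(np.arctan2(cross.sum(), dot.sum()))


def align_shape(
    shape: CorrespondedShape, reference: CorrespondedShape
) -> tuple[CorrespondedShape, AlignmentTransform]:
    """Rigidly align a shape to a corresponded reference.

    Translation is removed by matching centroids; rotation is corrected with
    the four-quadrant inverse tangent in two steps — the closed-form planar
    Procrustes angle first in the x-y plane, then in the x-z plane.  The
    returned transform inverts exactly.
    """
    if shape.K != reference.K:
        raise ValueError(f"vertex-count mismatch: {shape.K} vs {reference.K}")
    c_s = shape.centroid
    c_r = reference.centroid
    p = shape.vertices - c_s
    r = reference.vertices - c_r

    rot_xy = _procrustes_angle(p[:, [0, 1]], r[:, [0, 1]])
    p = _rotate_pair(p, 0, 1, rot_xy)
    rot_xz = _procrustes_angle(p[:, [0, 2]], r[:, [0, 2]])
    p = _rotate_pair(p, 0, 2, rot_xz)

    transform = AlignmentTransform(
        centroid=c_s, ref_centroid=c_r, rot_xy=float(rot_xy), rot_xz=float(rot_xz)
    )
    return CorrespondedShape(p + c_r), transform


# ---------------------------------------------------------------------------
# PCA shape model


def build_shape_model(
    shapes: list[CorrespondedShape], variance: float = 0.98
) -> ShapeModel:
    """PCA of aligned corresponded shapes, keeping ``variance`` of the total.

    Eigen-decomposition goes through the economy SVD of the (n x 3K) data
    matrix, i.e. the dual trick for n << 3K.
    """
    if len(shapes) < 3:
        raise ValueError("need at least 3 shapes for a PCA shape model")
    K = shapes[0].K
    if any(s.K != K for s in shapes):
        raise ValueError("all shapes must share the same vertex count")
    if not 0 < variance <= 1:
        raise ValueError("variance must be in (0, 1]")
    X = np.stack([s.as_vector() for s in shapes])  # (n, 3K)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (len(shapes) - 1)
    total = float(eigvals.sum())
    if total <= 1e-12:
        return ShapeModel(
            x_mean=x_mean,
            Ws=np.zeros((x_mean.size, 0)),
            eigenvalues=np.zeros(0),
            variance_retained=1.0,
            total_variance=0.0,
        )
    cum = np.cumsum(eigvals) / total
    t = int(np.searchsorted(cum, variance - 1e-12) + 1)
    t = min(t, len(eigvals))
    # drop numerically-zero trailing modes
    while t > 0 and eigvals[t - 1] < 1e-12 * eigvals[0]:
        t -= 1
    return ShapeModel(
        x_mean=x_mean,
        Ws=Vt[:t].T,
        eigenvalues=eigvals[:t],
        variance_retained=float(cum[t - 1]) if t > 0 else 0.0,
        total_variance=total,
    )
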