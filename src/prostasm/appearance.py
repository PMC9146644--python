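"""Gray-level appearance model along surface normals.

At every corresponded vertex, an intensity profile of length ``2*ns + 1`` is
sampled along the outward surface normal with cubic interpolation (``ns = 2``
by default, i.e. 5 samples at 0.5 mm steps, centred on the surface).  Across
the training cohort, profiles that do not belong to the dominant density
cluster (DBSCAN on z-normalized profiles) are discarded as noise, and a PCA
of the surviving profiles yields the mean profile and eigenstructure used by
the search objective.

Per-vertex statistics are kept by default (classic ASM); a pooled model over
all vertices serves as fallback for vertices with too few inliers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .shape import CorrespondedShape, SurfaceMesh
from .volume import Volume

DEFAULT_NS = 2
DEFAULT_STEP_MM = 0.5
DEFAULT_MIN_PTS = 8


class FilteringError(ValueError):
    """Density filtering rejected every profile."""


@dataclasses.dataclass(frozen=True)
class Profile:
    """One intensity profile: odd length, centre sample on the surface."""

    samples: np.ndarray
    vertex_index: int
    step: float = DEFAULT_STEP_MM

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size % 2 == 0:
            raise ValueError(f"profile must be 1D with odd length, got shape {s.shape}")
        if not np.all(np.isfinite(s)):
            raise ValueError("profile contains non-finite samples")
        object.__setattr__(self, "samples", s)

    @property
    def ns(self) -> int:
        return (self.samples.size - 1) // 2


@dataclasses.dataclass(frozen=True)
class VertexAppearance:
    """Mean profile and PCA eigenstructure for one vertex (or pooled)."""

    g_mean: np.ndarray  # (n,)
    Wg: np.ndarray  # (n, q)
    eigenvalues: np.ndarray  # (q,), descending, > 0

    @property
    def n(self) -> int:
        return self.g_mean.size


@dataclasses.dataclass(frozen=True)
class AppearanceModel:
    """Per-vertex appearance statistics with a pooled fallback.

    ``inlier_fraction`` records what fraction of training profiles survived
    the density filtering.
    """

    per_vertex: dict[int, VertexAppearance]
    pooled: VertexAppearance
    ns_model: int
    step: float
    inlier_fraction: float

    @property
    def n(self) -> int:
        return 2 * self.ns_model + 1

    def vertex(self, k: int) -> VertexAppearance:
        return self.per_vertex.get(k, self.pooled)


# ---------------------------------------------------------------------------
# normals and sampling


def _accumulate_vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted per-vertex normal accumulation, faces oriented outward.

    Triangle winding from the alpha shape is arbitrary; every face normal is
    flipped outward against the mesh centroid (star-shaped surface
    assumption) before accumulation, otherwise opposing windings cancel.
    """
    tc = mesh.triangle_coords()
    face_n = np.cross(tc[:, 1] - tc[:, 0], tc[:, 2] - tc[:, 0])  # area-weighted
    if np.linalg.norm(face_n, axis=1).max() < 1e-12:
        raise ValueError("degenerate mesh: all triangles have zero area")
    mesh_centroid = mesh.vertices.mean(axis=0)
    sign = np.einsum("ij,ij->i", face_n, tc.mean(axis=1) - mesh_centroid)
    face_n = face_n * np.where(sign < 0, -1.0, 1.0)[:, None]
    vert_n = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(vert_n, mesh.triangles[:, c], face_n)
    # two neighbour-averaging passes damp the sub-voxel surface jitter that
    # face-based normals inherit from the rasterized mask
    i = np.concatenate([mesh.triangles[:, 0], mesh.triangles[:, 1], mesh.triangles[:, 2]])
    j = np.concatenate([mesh.triangles[:, 1], mesh.triangles[:, 2], mesh.triangles[:, 0]])
    for _ in range(2):
        acc = vert_n.copy()
        np.add.at(acc, i, vert_n[j])
        np.add.at(acc, j, vert_n[i])
        vert_n = acc
    return vert_n


#: neighbourhood size of the local plane fit used for normal estimation
_NORMAL_FIT_K = 20


def surface_normals(shape: CorrespondedShape, mesh: SurfaceMesh) -> np.ndarray:
    """Outward unit normals at each corresponded vertex.

    Each vertex's normal is the smallest principal axis of a local PCA over
    its nearest mesh vertices (a plane fit, which damps the sub-voxel jitter
    that face-based normals inherit from rasterized surfaces), oriented
    outward against the shape centroid.  Vertices must lie on or near the
    mesh: the tolerance is 1 mm plus one median mesh edge, since corresponded
    vertices sit on faces rather than at mesh vertices.
    """
    vert_n = _accumulate_vertex_normals(mesh)  # validates mesh degeneracy
    del vert_n
    k = min(_NORMAL_FIT_K, len(mesh.vertices))
    nn = NearestNeighbors(n_neighbors=k).fit(mesh.vertices)
    dist, idx = nn.kneighbors(shape.vertices)
    edges = mesh.vertices[mesh.triangles[:, 1]] - mesh.vertices[mesh.triangles[:, 0]]
    # a point on a large face can be a full edge away from every vertex of
    # that face; scale the association limit with the coarse end of the
    # edge-length distribution
    limit = 1.0 + 2.0 * float(np.percentile(np.linalg.norm(edges, axis=1), 95))
    if dist[:, 0].max() > limit:
        worst = int(np.argmax(dist[:, 0]))
        raise ValueError(
            f"vertex {worst} is {dist[:, 0].max():.2f} mm from the mesh "
            f"(limit {limit:.2f} mm)"
        )
    normals = np.empty_like(shape.vertices)
    for v in range(shape.K):
        patch = mesh.vertices[idx[v]]
        centred = patch - patch.mean(axis=0)
        _w, vec = np.linalg.eigh(centred.T @ centred)
        normals[v] = vec[:, 0]  # smallest principal axis = plane normal

    radial = shape.vertices - shape.centroid
    outward = np.einsum("ij,ij->i", normals, radial)
    sign = np.where(outward < 0, -1.0, 1.0)
    zero = np.abs(outward) < 1e-12
    normals = normals * sign[:, None]
    normals[zero] = radial[zero] / np.maximum(
        np.linalg.norm(radial[zero], axis=1, keepdims=True), 1e-12
    )
    return normals


def sample_profile(
    vol: Volume,
    point: np.ndarray,
    normal: np.ndarray,
    ns: int = DEFAULT_NS,
    step: float = DEFAULT_STEP_MM,
    vertex_index: int = 0,
) -> Profile:
    """Sample ``2*ns + 1`` intensities along a normal, cubic interpolation.

    Out-of-extent positions take the edge value (same policy as resampling).
    """
    samples = sample_line(vol, point, normal, ns, step)
    return Profile(samples=samples, vertex_index=vertex_index, step=step)


def sample_line(
    vol: Volume, point: np.ndarray, normal: np.ndarray, half_len: int, step: float
) -> np.ndarray:
    """Raw cubic-interpolated samples at ``point + k*step*normal``, k=-h..+h."""
    return sample_lines(vol, np.asarray(point)[None, :], np.asarray(normal)[None, :],
                        half_len, step)[0]


def sample_lines(
    vol: Volume,
    points: np.ndarray,
    normals: np.ndarray,
    half_len: int,
    step: float,
) -> np.ndarray:
    """Cubic-interpolated samples along many normals in one pass.

    Returns an (N, 2*half_len + 1) array; one interpolation call covers all
    lines, which matters because cubic interpolation spline-filters the
    source volume once per call.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    norms = np.linalg.norm(normals, axis=1)
    if np.abs(norms - 1.0).max() > 1e-6:
        raise ValueError("normals must be unit length")
    offsets = np.arange(-half_len, half_len + 1)
    # (N, L, 3) sample positions
    pts = points[:, None, :] + offsets[None, :, None] * step * normals[:, None, :]
    idx = vol.physical_to_index(pts.reshape(-1, 3))
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), idx.T, order=3, mode="nearest"
    )
    return out.reshape(points.shape[0], offsets.size)


# ---------------------------------------------------------------------------
# DBSCAN noise rejection


def _z_normalize(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def _kdistance_elbow(feats: np.ndarray, k: int) -> float:
    """eps from the sorted k-distance curve (point of maximum curvature)."""
    k = min(k, len(feats) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(feats)
    dist, _ = nn.kneighbors(feats)
    kd = np.sort(dist[:, -1])
    if kd[-1] <= 0:
        return 1e-6
    if len(kd) < 3:
        return float(kd[-1]) * 1.5
    second_diff = np.diff(kd, 2)
    elbow = int(np.argmax(second_diff)) + 1
    eps = float(kd[elbow])
    return max(eps, float(np.median(kd)), 1e-6)


def filter_profiles_dbscan(
    profiles: list[Profile],
    eps: float | None = None,
    min_pts: int = DEFAULT_MIN_PTS,
) -> tuple[list[Profile], list[Profile]]:
    """Split profiles into (inliers, outliers) by density clustering.

    Distances are Euclidean between per-profile z-normalized sample vectors;
    inliers are the members of the largest DBSCAN cluster, everything else
    (noise points and minor clusters) is an outlier.  When ``eps`` is not
    given it is chosen from the k-distance elbow with k = ``min_pts``.
    """
    if eps is not None and eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if len(profiles) < min_pts:
        raise ValueError(f"need at least min_pts={min_pts} profiles, got {len(profiles)}")
    feats = _z_normalize(np.stack([p.samples for p in profiles]))
    if eps is None:
        eps = _kdistance_elbow(feats, min_pts)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(feats)
    cluster_ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
    if cluster_ids.size == 0:
        raise FilteringError(
            f"all {len(profiles)} profiles labelled noise at eps={eps:.3g}; "
            "try a larger eps"
        )
    main = cluster_ids[np.argmax(sizes)]
    inliers = [p for p, lab in zip(profiles, labels) if lab == main]
    outliers = [p for p, lab in zip(profiles, labels) if lab != main]
    return inliers, outliers


# ---------------------------------------------------------------------------
# PCA appearance model


#: appearance modes carrying less than this fraction of the leading
#: eigenvalue are dropped: the objective divides by eigenvalues, so
#: numerically negligible modes would otherwise dominate the cost
_EIG_REL_FLOOR = 1e-4


def _pca_profiles(mat: np.ndarray) -> VertexAppearance:
    g_mean = mat.mean(axis=0)
    Xc = mat - g_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / max(len(mat) - 1, 1)
    keep = eigvals > max(1e-12, _EIG_REL_FLOOR * (eigvals[0] if eigvals.size else 0.0))
    q = min(int(keep.sum()), mat.shape[1] - 1)
    return VertexAppearance(g_mean=g_mean, Wg=Vt[:q].T, eigenvalues=eigvals[:q])


def build_appearance_model(
    profiles_by_vertex: dict[int, list[Profile]],
    min_per_vertex: int = 3,
    inlier_fraction: float = 1.0,
    step: float = DEFAULT_STEP_MM,
) -> AppearanceModel:
    """PCA of inlier profiles: per-vertex models with a pooled fallback.

    ``profiles_by_vertex`` maps vertex index to that vertex's inlier profiles
    (after density filtering).  Vertices with fewer than ``min_per_vertex``
    profiles fall back to the pooled model at lookup time.
    """
    all_profiles = [p for plist in profiles_by_vertex.values() for p in plist]
    if len(all_profiles) < 3:
        raise ValueError("need at least 3 inlier profiles overall")
    lengths = {p.samples.size for p in all_profiles}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent profile lengths: {sorted(lengths)}")
    n = lengths.pop()
    ns_model = (n - 1) // 2

    pooled = _pca_profiles(np.stack([p.samples for p in all_profiles]))
    per_vertex = {
        k: _pca_profiles(np.stack([p.samples for p in plist]))
        for k, plist in profiles_by_vertex.items()
        if len(plist) >= min_per_vertex
    }
    return AppearanceModel(
        per_vertex=per_vertex,
        pooled=pooled,
        ns_model=ns_model,
        step=step,
        inlier_fraction=float(inlier_fraction),
    )
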