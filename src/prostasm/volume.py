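"""Volume and mask containers plus NIfTI I/O and grid resampling.

All spatial quantities in this package live in one frame: voxel indices are
0-based, the physical position of voxel ``(i, j, k)`` is
``origin + index * spacing`` (millimetres), and every mesh / vertex coordinate
downstream is expressed in this physical frame.  Images are stored as plain
``numpy`` arrays indexed ``(x, y, z)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclasses.dataclass(frozen=True)
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Voxel size ``(sx, sy, sz)`` in mm, all strictly positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if data.size == 0:
            raise ValueError("volume array is empty")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N, 3) to mm coordinates (N, 3)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates (N, 3) to fractional voxel indices (N, 3)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclasses.dataclass(frozen=True)
class BinaryMask(Volume):
    """A Volume whose voxels are 0/1 labels (stored uint8)."""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {uniq[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8))
        super().__post_init__()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI volume; spacing/origin come from the affine.

    Oblique affines (off-diagonal rotation terms) are rejected: this package
    works in an axis-aligned physical frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except nib.filebasedimages.ImageFileError as exc:
        raise ValueError(f"{path} is not a recognized 3D image format") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    aff = img.affine
    rot = aff[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-4 * max(1.0, np.abs(rot).max()):
        raise ValueError(f"{path}: oblique affine not supported:\n{rot}")
    spacing = tuple(np.abs(np.diag(rot)))
    origin = tuple(aff[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume (float32) or BinaryMask (uint8) as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if isinstance(vol, BinaryMask) else np.float32
    img = nib.Nifti1Image(vol.data.astype(dtype), _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _resample(vol: Volume, spacing, origin, shape, mode: str) -> np.ndarray:
    """Sample vol at the grid defined by (spacing, origin, shape)."""
    if mode not in ("cubic", "nearest"):
        raise ValueError(f"mode must be 'cubic' or 'nearest', got {mode!r}")
    idx = [
        (origin[a] + spacing[a] * np.arange(shape[a]) - vol.origin[a]) / vol.spacing[a]
        for a in range(3)
    ]
    if mode == "nearest":
        # separable nearest-neighbour gather (exact and much faster than a
        # full coordinate map for axis-aligned grids)
        near = [
            np.clip(np.round(idx[a]).astype(int), 0, vol.shape[a] - 1) for a in range(3)
        ]
        return vol.data[np.ix_(*near)].astype(np.float64)
    grids = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), coords, order=3, mode="nearest"
    )
    return out.reshape(shape)


def resample_isotropic(vol: Volume, target: float = 0.5, mode: str = "cubic"):
    """Resample to an isotropic grid of voxel size ``target`` mm.

    Physical extent is preserved to within one voxel; masks must use
    ``mode='nearest'`` so the {0, 1} value set survives.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    new_shape = tuple(
        max(1, int(round(vol.shape[a] * vol.spacing[a] / target))) for a in range(3)
    )
    spacing = (target, target, target)
    data = _resample(vol, spacing, vol.origin, new_shape, mode)
    if isinstance(vol, BinaryMask):
        if mode != "nearest":
            raise ValueError("binary masks must be resampled with mode='nearest'")
        return BinaryMask(data > 0.5, spacing, vol.origin)
    return Volume(data, spacing, vol.origin)


def resample_to_grid(vol: Volume, reference: Volume, mode: str = "cubic"):
    """Resample ``vol`` onto the voxel grid of ``reference``."""
    lo_v = np.asarray(vol.origin)
    hi_v = lo_v + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    lo_r = np.asarray(reference.origin)
    hi_r = lo_r + (np.asarray(reference.shape) - 1) * np.asarray(reference.spacing)
    if np.any(hi_v < lo_r) or np.any(lo_v > hi_r):
        warnings.warn("physical extents are disjoint; output is zero-filled")
        data = np.zeros(reference.shape)
    else:
        data = _resample(vol, reference.spacing, reference.origin, reference.shape, mode)
    if isinstance(vol, BinaryMask):
        if mode != "nearest":
            raise ValueError("binary masks must be resampled with mode='nearest'")
        return BinaryMask(data > 0.5, reference.spacing, reference.origin)
    return Volume(data, reference.spacing, reference.origin)
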