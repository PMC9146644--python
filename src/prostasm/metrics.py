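"""Segmentation quality metrics: DSC, 95th-percentile Hausdorff distance, RVD.

Surface voxels are defined by the 6-connectivity erosion difference; surface
distances use the Euclidean distance transform with anisotropic physical
spacing, so HD95 is reported in millimetres on whatever grid the masks live on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, GridError

_CROSS6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    dsc: float
    hd95_mm: float
    rvd_percent: float

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "hd95_mm": self.hd95_mm, "rvd_percent": self.rvd_percent}


def _check_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_grid(b):
        raise GridError(
            f"masks are on different grids: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 if both empty."""
    _check_grid(a, b)
    fa = a.data.astype(bool)
    fb = b.data.astype(bool)
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(fa, fb).sum()) / denom


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking foreground voxels with a 6-neighbour outside."""
    fg = mask.data.astype(bool)
    eroded = ndimage.binary_erosion(fg, structure=_CROSS6, border_value=0)
    return fg & ~eroded


def _directed_hd95(surf_a: np.ndarray, surf_b: np.ndarray, spacing) -> float:
    # distance from every a-surface voxel to the nearest b-surface voxel
    dt_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dists = dt_b[surf_a]
    return float(np.percentile(dists, 95))


def hd95(a: BinaryMask, b: BinaryMask, directed: bool = False) -> float:
    """Symmetrised 95th-percentile Hausdorff distance in mm.

    ``directed=True`` returns only the a→b directed value.
    """
    _check_grid(a, b)
    if a.data.sum() == 0 or b.data.sum() == 0:
        raise ValueError("hd95 requires two non-empty masks")
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    d_ab = _directed_hd95(sa, sb, a.spacing)
    if directed:
        return d_ab
    d_ba = _directed_hd95(sb, sa, a.spacing)
    return max(d_ab, d_ba)


def rvd(auto: BinaryMask, ref: BinaryMask) -> float:
    """Relative volume difference 100·(V_auto − V_ref)/V_ref; positive means
    over-segmentation of ``auto`` relative to the reference."""
    _check_grid(auto, ref)
    v_ref = int(ref.data.sum())
    if v_ref == 0:
        raise ValueError("reference mask is empty")
    v_auto = int(auto.data.sum())
    return 100.0 * (v_auto - v_ref) / v_ref


def evaluate(auto: BinaryMask, ref: BinaryMask) -> MetricsReport:
    """All three metrics of one auto/reference mask pair."""
    return MetricsReport(dsc=dsc(auto, ref), hd95_mm=hd95(auto, ref), rvd_percent=rvd(auto, ref))
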