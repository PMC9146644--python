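"""Bias-field correction and inter-volume intensity standardization.

MR intensities have no fixed meaning across scanners and sessions, and are
corrupted by a smooth multiplicative non-uniformity (bias field).  Two
corrections are applied before any appearance statistics are learned:

1. N4 bias-field correction (delegated to SimpleITK's implementation), with a
   foreground mask from Otsu thresholding.  The observed image is modelled as
   ``v = u * f + n`` with a smooth positive field ``f``; the correction
   accumulates per-iteration residual fields in the log domain.
2. Piecewise-linear histogram standardization in the Nyul-Udupa style: learn
   mean landmark positions on a standard scale from the training cohort, then
   map each volume's landmarks exactly onto those positions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume import Volume

DEFAULT_PERCENTILES = (1.0, 10.0, 25.0, 50.0, 75.0, 90.0, 99.0)
DEFAULT_OUTPUT_RANGE = (0.0, 4095.0)


class DegenerateHistogramError(ValueError):
    """The volume has too few distinct intensities to standardize."""


@dataclasses.dataclass(frozen=True)
class StandardScale:
    """Learned standard intensity scale.

    ``landmark_percentiles`` are the percentile ranks used as landmarks; the
    first and last double as the anchors mapped affinely onto
    ``output_range`` before averaging across the cohort.
    """

    landmark_percentiles: tuple[float, ...]
    standard_positions: tuple[float, ...]
    output_range: tuple[float, float] = DEFAULT_OUTPUT_RANGE

    def __post_init__(self) -> None:
        lp = tuple(float(p) for p in self.landmark_percentiles)
        sp = tuple(float(s) for s in self.standard_positions)
        if len(lp) != len(sp) or len(lp) < 2:
            raise ValueError("landmark lists must have equal length >= 2")
        if np.any(np.diff(lp) <= 0) or np.any(np.diff(sp) <= 0):
            raise ValueError("landmark lists must be strictly increasing")
        if not self.output_range[0] < self.output_range[1]:
            raise ValueError("output_range must satisfy smin < smax")
        object.__setattr__(self, "landmark_percentiles", lp)
        object.__setattr__(self, "standard_positions", sp)
        object.__setattr__(self, "output_range", tuple(float(v) for v in self.output_range))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "StandardScale":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["landmark_percentiles"]),
            tuple(d["standard_positions"]),
            tuple(d["output_range"]),
        )


@dataclasses.dataclass(frozen=True)
class BiasModel:
    """Estimated multiplicative field (mean ~ 1 inside the mask)."""

    field: np.ndarray
    n_iterations: int


def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float64))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    return img


def _from_sitk(img: sitk.Image, like: Volume) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T.copy()


def correct_bias_field(
    vol: Volume,
    max_iterations: int = 50,
    shrink_factor: int = 4,
    fitting_levels: int = 4,
) -> tuple[Volume, BiasModel]:
    """Remove smooth multiplicative intensity non-uniformity with N4.

    The field is estimated on a shrunk copy for speed, reconstructed on the
    full grid from the log bias field, normalized to unit mean inside the
    Otsu foreground mask, and divided out everywhere.
    """
    data = vol.data
    if np.any(data < 0):
        raise ValueError("bias correction expects non-negative intensities")
    if not np.any(data > 0):
        raise ValueError("degenerate input: volume is identically zero")

    img = _to_sitk(vol)
    mask_img = sitk.OtsuThreshold(img, 0, 1)

    shrunk = sitk.Shrink(img, [shrink_factor] * 3)
    shrunk_mask = sitk.Shrink(mask_img, [shrink_factor] * 3)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([int(max_iterations)] * fitting_levels)
    n4.Execute(shrunk, shrunk_mask)
    log_field = n4.GetLogBiasFieldAsImage(img)
    field = np.exp(_from_sitk(log_field, vol))

    fg = _from_sitk(mask_img, vol).astype(bool)
    if fg.any():
        field = field / field[fg].mean()
    corrected = data / field
    return (
        Volume(corrected, vol.spacing, vol.origin),
        BiasModel(field=field, n_iterations=int(max_iterations)),
    )


def _volume_landmarks(vol: Volume, percentiles) -> np.ndarray:
    """Landmark intensities of one volume (percentiles of all voxels)."""
    data = np.asarray(vol.data, dtype=float).ravel()
    if np.ptp(data) == 0:
        raise DegenerateHistogramError("constant-intensity volume has no landmarks")
    marks = np.percentile(data, percentiles)
    if np.unique(marks).size < len(marks):
        raise DegenerateHistogramError(
            "fewer distinct intensities than landmarks; histogram too coarse"
        )
    return marks


def foreground_mode(vol: Volume, bins: int = 128) -> float:
    """Histogram mode of the above-p1 (foreground-dominated) intensities.

    Exposed as a reference point for scale inspection; it is deliberately not
    a default landmark because its rank order relative to fixed percentiles
    varies across subjects, which would break the monotone landmark
    correspondence of the piecewise-linear map.
    """
    data = np.asarray(vol.data, dtype=float).ravel()
    fg = data[data > np.percentile(data, 1)]
    hist, edges = np.histogram(fg, bins=bins)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def learn_standard_scale(
    volumes: list[Volume],
    percentiles=DEFAULT_PERCENTILES,
    output_range=DEFAULT_OUTPUT_RANGE,
) -> StandardScale:
    """Learn the standard scale from a training cohort.

    Each volume's (p_low, p_high) anchor pair is mapped affinely onto
    ``output_range``; standard positions are the across-volume means of the
    mapped landmarks, so volumes differing only by an affine intensity
    transform contribute identical mapped landmarks.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two training volumes to learn a scale")
    percentiles = tuple(float(p) for p in percentiles)
    smin, smax = output_range
    mapped = []
    for vol in volumes:
        marks = _volume_landmarks(vol, percentiles)
        lo, hi = marks[0], marks[-1]
        mapped.append(smin + (marks - lo) * (smax - smin) / (hi - lo))
    positions = np.mean(mapped, axis=0)
    return StandardScale(percentiles, tuple(positions), tuple(output_range))


def standardize_intensity(vol: Volume, scale: StandardScale) -> Volume:
    """Map a volume onto the standard scale by piecewise-linear interpolation.

    Each landmark intensity maps exactly onto its standard position; between
    landmarks the map is linear, and beyond the terminal landmarks the
    terminal segments are extended.
    """
    marks = _volume_landmarks(vol, scale.landmark_percentiles)
    pos = np.asarray(scale.standard_positions)
    data = np.asarray(vol.data, dtype=float)
    out = np.interp(data, marks, pos)
    # extend terminal segments instead of clamping
    lo_slope = (pos[1] - pos[0]) / (marks[1] - marks[0])
    hi_slope = (pos[-1] - pos[-2]) / (marks[-1] - marks[-2])
    below = data < marks[0]
    above = data > marks[-1]
    out[below] = pos[0] + (data[below] - marks[0]) * lo_slope
    out[above] = pos[-1] + (data[above] - marks[-1]) * hi_slope
    return Volume(out, vol.spacing, vol.origin)
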