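"""End-to-end orchestration: model building and segmentation refinement.

``build_models`` turns a training cohort of (volume, mask) pairs into one
portable model archive (shape PCA + appearance statistics + ray
configuration); ``run_pipeline`` applies an initializer to a new volume and
refines its output against the archive.  Both work on the 0.5 mm isotropic
grid internally and return results on the native grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .appearance import (
    AppearanceModel,
    Profile,
    VertexAppearance,
    build_appearance_model,
    filter_profiles_dbscan,
    sample_lines,
    surface_normals,
)
from .cnn import initial_segmentation
from .engine import DEFAULT_CONFIG, PRESETS, ASMConfig, refine
from .metrics import MetricsReport, evaluate
from .postprocess import clean_mask, shape_to_mask
from .shape import (
    CorrespondedShape,
    RayConfig,
    ShapeModel,
    align_shape,
    build_shape_model,
    extract_corresponded_vertices,
)
from .volume import BinaryMask, Volume, resample_isotropic

ISO_SPACING_MM = 0.5


class CompatibilityError(ValueError):
    """Model archive and requested configuration disagree (e.g. on K)."""


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything a refinement run needs besides the inputs."""

    asm: ASMConfig = DEFAULT_CONFIG
    ray_config: RayConfig = RayConfig()
    target_spacing: float = ISO_SPACING_MM
    postprocess_alpha: float = 30.0
    closing_radius_vox: int = 4
    dbscan_min_pts: int = 8
    dbscan_eps: float | None = None
    variance: float = 0.98
    seed: int = 0

    @classmethod
    def with_preset(cls, name: str, **kwargs) -> "PipelineConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return cls(asm=PRESETS[name], **kwargs)


@dataclasses.dataclass(frozen=True)
class ModelArchive:
    """Shape + appearance model bundle with shared ray configuration."""

    shape_model: ShapeModel
    appearance_model: AppearanceModel
    ray_config: RayConfig
    provenance: dict

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {
            "x_mean": self.shape_model.x_mean,
            "Ws": self.shape_model.Ws,
            "lambda_s": self.shape_model.eigenvalues,
            "pooled_g_mean": self.appearance_model.pooled.g_mean,
            "pooled_Wg": self.appearance_model.pooled.Wg,
            "pooled_lambda_g": self.appearance_model.pooled.eigenvalues,
        }
        for k, va in self.appearance_model.per_vertex.items():
            arrays[f"v{k}_g_mean"] = va.g_mean
            arrays[f"v{k}_Wg"] = va.Wg
            arrays[f"v{k}_lambda_g"] = va.eigenvalues
        np.savez_compressed(path / "arrays.npz", **arrays)
        meta = {
            "version": __version__,
            "variance_retained": self.shape_model.variance_retained,
            "total_variance": self.shape_model.total_variance,
            "ns_model": self.appearance_model.ns_model,
            "step": self.appearance_model.step,
            "inlier_fraction": self.appearance_model.inlier_fraction,
            "per_vertex_keys": sorted(self.appearance_model.per_vertex),
            "ray_config": {
                "n_azimuths": self.ray_config.n_azimuths,
                "elevations_deg": list(self.ray_config.elevations_deg),
                "alpha": self.ray_config.alpha,
                "max_surface_points": self.ray_config.max_surface_points,
            },
            "provenance": self.provenance,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "ModelArchive":
        path = Path(path)
        if not (path / "meta.json").exists():
            raise FileNotFoundError(f"no model archive at {path}")
        meta = json.loads((path / "meta.json").read_text())
        with np.load(path / "arrays.npz") as z:
            arrays = {k: z[k] for k in z.files}
        smodel = ShapeModel(
            x_mean=arrays["x_mean"],
            Ws=arrays["Ws"],
            eigenvalues=arrays["lambda_s"],
            variance_retained=meta["variance_retained"],
            total_variance=meta["total_variance"],
        )
        per_vertex = {
            int(k): VertexAppearance(
                g_mean=arrays[f"v{k}_g_mean"],
                Wg=arrays[f"v{k}_Wg"],
                eigenvalues=arrays[f"v{k}_lambda_g"],
            )
            for k in meta["per_vertex_keys"]
        }
        amodel = AppearanceModel(
            per_vertex=per_vertex,
            pooled=VertexAppearance(
                g_mean=arrays["pooled_g_mean"],
                Wg=arrays["pooled_Wg"],
                eigenvalues=arrays["pooled_lambda_g"],
            ),
            ns_model=meta["ns_model"],
            step=meta["step"],
            inlier_fraction=meta["inlier_fraction"],
        )
        rc = meta["ray_config"]
        ray_config = RayConfig(
            n_azimuths=rc["n_azimuths"],
            elevations_deg=tuple(rc["elevations_deg"]),
            alpha=rc["alpha"],
            max_surface_points=rc["max_surface_points"],
        )
        return cls(smodel, amodel, ray_config, meta.get("provenance", {}))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def build_models(
    pairs: list[tuple[Volume, BinaryMask]],
    config: PipelineConfig = PipelineConfig(),
) -> ModelArchive:
    """Build the shape + appearance archive from (volume, mask) pairs.

    Masks and volumes are resampled to the isotropic working grid;
    corresponded vertices are extracted per member and aligned to the first
    member; the shape PCA keeps ``config.variance`` of total variance.
    Appearance profiles are sampled per vertex on each member's volume,
    density-filtered over the pooled profile set, and turned into per-vertex
    PCA statistics with a pooled fallback.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 training pairs (PCA precondition)")
    t0 = time.time()
    shapes: list[CorrespondedShape] = []
    profiles: list[Profile] = []
    for i, (vol, mask) in enumerate(pairs):
        iso_mask = resample_isotropic(mask, config.target_spacing, mode="nearest")
        iso_vol = resample_isotropic(vol, config.target_spacing, mode="cubic")
        shape, mesh = extract_corresponded_vertices(
            iso_mask, config.ray_config, return_mesh=True
        )
        if i == 0:
            shapes.append(shape)
        else:
            aligned, _ = align_shape(shape, shapes[0])
            shapes.append(aligned)
        # normals on the dense extraction mesh (the vertices lie on it)
        normals = surface_normals(shape, mesh)
        samples = sample_lines(
            iso_vol, shape.vertices, normals, config.asm.ns_model, config.target_spacing
        )
        for k in range(shape.K):
            profiles.append(
                Profile(samples=samples[k], vertex_index=k, step=config.target_spacing)
            )

    inliers, outliers = filter_profiles_dbscan(
        profiles, eps=config.dbscan_eps, min_pts=config.dbscan_min_pts
    )
    by_vertex: dict[int, list[Profile]] = {}
    for p in inliers:
        by_vertex.setdefault(p.vertex_index, []).append(p)
    amodel = build_appearance_model(
        by_vertex,
        inlier_fraction=len(inliers) / len(profiles),
        step=config.target_spacing,
    )
    smodel = build_shape_model(shapes, config.variance)
    provenance = {
        "n_training_pairs": len(pairs),
        "config_hash": _config_hash(config),
        "K": config.ray_config.K,
        "alpha_correspondence": config.ray_config.alpha,
        "variance": config.variance,
        "dbscan_min_pts": config.dbscan_min_pts,
        "inlier_fraction": len(inliers) / len(profiles),
        "build_seconds": round(time.time() - t0, 2),
    }
    return ModelArchive(smodel, amodel, config.ray_config, provenance)


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    mask: BinaryMask
    initial_mask: BinaryMask
    refined_shape: CorrespondedShape
    report: MetricsReport | None
    provenance: dict


def run_pipeline(
    vol: Volume,
    initializer,
    archive: ModelArchive,
    config: PipelineConfig = PipelineConfig(),
    reference_mask: BinaryMask | None = None,
) -> PipelineResult:
    """Initializer → correspondence → ASM refinement → final mask.

    If ``reference_mask`` is given, a :class:`MetricsReport` against it (on
    the native grid) is attached to the result.
    """
    if archive.ray_config.K != config.ray_config.K:
        raise CompatibilityError(
            f"archive K={archive.ray_config.K} != configured K={config.ray_config.K}"
        )
    t0 = time.time()
    init_mask = initial_segmentation(vol, initializer)
    iso_vol = resample_isotropic(vol, config.target_spacing, mode="cubic")
    iso_init = resample_isotropic(init_mask, config.target_spacing, mode="nearest")
    iso_init = clean_mask(iso_init)
    init_shape = extract_corresponded_vertices(iso_init, archive.ray_config)
    refined = refine(
        iso_vol, init_shape, archive.shape_model, archive.appearance_model, config.asm
    )
    final = shape_to_mask(
        refined,
        iso_vol,
        reference=vol,
        alpha=config.postprocess_alpha,
        closing_radius_vox=config.closing_radius_vox,
    )
    report = None
    if reference_mask is not None:
        report = evaluate(final, reference_mask)
    provenance = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "asm": dataclasses.asdict(config.asm),
        "K": archive.ray_config.K,
        "run_seconds": round(time.time() - t0, 2),
    }
    return PipelineResult(
        mask=final,
        initial_mask=init_mask,
        refined_shape=refined,
        report=report,
        provenance=provenance,
    )
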