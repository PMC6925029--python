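"""File formats and pipeline configuration.

Frames travel as multipage TIFF (page order DAPI, CK, CD45, CDX2; integer
pixels preserved bit-exact) with a JSON sidecar holding frame metadata and
ground-truth object records; label masks as a 2-page 16-bit TIFF (nuclear,
cell). Cohorts are UTF-8 comma CSVs with the mandated annotation columns.
The pipeline configuration is a schema-validated YAML document; unknown keys
are rejected so silently ignored typos cannot change an analysis.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from .catalog import CHANNELS
from .synthetic import FrameScene, FrameSceneSpec

__all__ = [
    "write_frame",
    "read_frame",
    "write_masks",
    "read_masks",
    "PipelineConfig",
    "load_config",
]


def write_frame(scene: FrameScene, path: str | Path, sidecar: bool = True) -> Path:
    """Write channels as a 4-page TIFF; masks and a JSON sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, scene.channel_stack(), photometric="minisblack")
    write_masks(scene, path.with_name(path.stem + "_masks.tif"))
    if sidecar:
        spec = dataclasses.asdict(scene.spec)
        spec["channel_levels"] = {k: dict(v) for k, v in spec["channel_levels"].items()}
        spec["background_level"] = dict(spec["background_level"])
        meta = {
            "channel_order": list(CHANNELS),
            "spec": spec,
            "objects": [dataclasses.asdict(o) for o in scene.objects],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=list))
    return path


def write_masks(scene: FrameScene, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack(
            [scene.nuclear_labels.astype(np.uint16), scene.cell_labels.astype(np.uint16)]
        ),
        photometric="minisblack",
    )
    return path


def read_masks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError("mask TIFF must have exactly 2 pages (nuclear, cell)")
    return stack[0], stack[1]


def read_frame(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a 4-page frame TIFF and its sidecar.

    Returns (channels keyed by channel name, metadata). A missing sidecar
    falls back to the default channel order with a warning; a page count
    other than 4 is an error.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != len(CHANNELS):
        raise ValueError(
            f"frame TIFF must have exactly {len(CHANNELS)} pages "
            f"(order {', '.join(CHANNELS)}); got shape {stack.shape}"
        )
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        order = meta.get("channel_order", list(CHANNELS))
        if sorted(order) != sorted(CHANNELS):
            raise ValueError(f"sidecar channel order {order} does not match {CHANNELS}")
    else:
        warnings.warn(
            f"no sidecar {sidecar.name}; assuming channel order {CHANNELS}",
            stacklevel=2,
        )
        meta = {"channel_order": list(CHANNELS)}
        order = list(CHANNELS)
    channels = {name: stack[i] for i, name in enumerate(order)}
    return channels, meta


def scene_from_files(frame_path: str | Path) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, dict]:
    """Channels + masks + metadata for a frame written by :func:`write_frame`."""
    frame_path = Path(frame_path)
    channels, meta = read_frame(frame_path)
    nuclear, cell = read_masks(frame_path.with_name(frame_path.stem + "_masks.tif"))
    return channels, nuclear, cell, meta


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationConfig(_Strict):
    min_area_px: int = 20
    fallback_dilation_px: int = 4
    threshold_method: str = "otsu"
    split_h: float = 2.0


class ClassifierThresholds(_Strict):
    t_ck: float = 5.0
    t_cd45: float = 3.0
    size_factor: float = 1.25
    solidity_min: float = 0.85
    cdx2_sdom_threshold: float = 5.0


class ClusteringConfig(_Strict):
    metric: str = "euclidean"
    linkage: str = "complete"
    cell_level: int = 3
    meta_level: int = 2


class PowerConfig(_Strict):
    alpha: float = 0.05
    power: float = 0.8
    alternative: str = "two-sided"


class InclusionConfig(_Strict):
    min_liquid: int = 20
    min_clusters: int = 4
    strict_clusters: bool = False


class CohortSimConfig(_Strict):
    n_patients: int = 3
    compartments: list[str] = ["liquid", "metastasis"]
    cells_per_compartment: int = 43
    n_features: int = 82
    within_sd: float = 1.0
    shift_scale: float = 0.2
    target_profile_correlation: float = 0.65


class FrameSimConfig(_Strict):
    enabled: bool = False
    n_frames: int = 2
    frame_shape: list[int] = [400, 400]
    n_wbc: int = 60
    n_tumor: int = 5
    n_tumor_clusters: int = 1
    cluster_size: int = 2
    tumor_nuclear_scale: float = 1.6
    cdx2_positive_fraction: float = 0.5
    leukocyte_concentration: float = 5.0e6  # cells/mL
    n_dapi_nuclei: int = 1_000_000  # per slide


class PipelineConfig(_Strict):
    """Declarative document holding every stage parameter and the seed."""

    seed: int = 0
    segmentation: SegmentationConfig = SegmentationConfig()
    classifier: ClassifierThresholds = ClassifierThresholds()
    clustering: ClusteringConfig = ClusteringConfig()
    power: PowerConfig = PowerConfig()
    inclusion: InclusionConfig = InclusionConfig()
    cohort: CohortSimConfig = CohortSimConfig()
    frames: FrameSimConfig = FrameSimConfig()
    cohort_csv: str | None = None  # analyse an existing table instead of simulating
    figures: bool = False


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML configuration (defaults when path is None)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def frame_spec_from_config(cfg: FrameSimConfig, seed: int) -> FrameSceneSpec:
    return FrameSceneSpec(
        frame_shape=tuple(cfg.frame_shape),
        n_wbc=cfg.n_wbc,
        n_tumor=cfg.n_tumor,
        n_tumor_clusters=cfg.n_tumor_clusters,
        cluster_size=cfg.cluster_size,
        tumor_nuclear_scale=cfg.tumor_nuclear_scale,
        cdx2_positive_fraction=cfg.cdx2_positive_fraction,
        seed=seed,
    )
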