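"""End-to-end CT-based node segmentation.

The stage order is fixed: k-means tissue clustering -> fat-cluster removal
(binary node mask) -> container-case removal by radial distance -> erosion ->
hole-filling -> slice-wise 2D small-feature removal -> dilation -> 3D
small-component removal -> connected-component labeling. Erosion precedes
filling so detached noise does not seal cavities shut; dilation compensates
the erosion with an equal-radius element by default. An empty final mask is a
result ("no nodes found"), never an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import io as vio
from .clustering import ClusteringConfig, assign_clusters, extract_node_mask, fit_kmeans_1d
from .grid import LabelMask, VolumeGrid
from .morphology import (
    CaseGeometry,
    StructuringElement,
    dilate,
    erode,
    estimate_case_geometry,
    fill_holes,
    filter_small_2d,
    filter_small_3d,
    label_components,
    remove_case,
)

__all__ = ["SegmentationConfig", "StageTrace", "segment_nodes", "run_from_files"]

STAGE_ORDER = (
    "node_cluster",
    "case_removal",
    "erosion",
    "filling",
    "filter_2d",
    "dilation",
    "filter_3d",
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Every tunable of the segmentation pipeline, fully defaulted.

    ``case`` is a fixed :class:`CaseGeometry`, the string ``"auto"`` (smallest
    enclosing cylinder of the non-air support, with ``case_margin`` mm
    stripped inside the wall), or ``None`` to skip case removal.
    """

    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    case: CaseGeometry | str | None = "auto"
    case_margin: float = 0.8  # mm stripped inside the estimated wall (auto mode)
    element_shape: str = "ball"
    erosion_radius: int = 2
    dilation_radius: int = 2
    fill_slicewise: bool = False
    min_pixels_2d: int = 20
    min_voxels_3d: int = 500
    connectivity_2d: int = 8
    connectivity_3d: int = 26
    slice_axis: int = 2

    def __post_init__(self):
        if self.erosion_radius < 1 or self.dilation_radius < 1:
            raise ValueError("erosion_radius and dilation_radius must be >= 1")
        if self.min_pixels_2d < 1 or self.min_voxels_3d < 1:
            raise ValueError("min_pixels_2d and min_voxels_3d must be >= 1")
        if isinstance(self.case, str) and self.case != "auto":
            raise ValueError(f"case must be a CaseGeometry, 'auto' or None, got {self.case!r}")


@dataclass
class StageTrace:
    """Per-stage foreground voxel and component counts, in pipeline order."""

    stages: list[dict] = field(default_factory=list)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    case_geometry: CaseGeometry | None = None
    model_centroids: list[float] | None = None

    def record(self, name: str, mask: LabelMask, connectivity: int, keep_mask: bool):
        arr = mask.as_bool()
        n_comp = int(label_components(arr, connectivity).max(initial=0))
        self.stages.append(
            {"stage": name, "foreground_voxels": int(arr.sum()), "components": n_comp}
        )
        if keep_mask:
            self.masks[name] = arr.copy()

    def to_dict(self) -> dict:
        out = {"stages": self.stages}
        if self.model_centroids is not None:
            out["kmeans_centroids"] = self.model_centroids
        if self.case_geometry is not None:
            g = self.case_geometry
            out["case_geometry"] = {
                "axis": g.axis, "center": list(g.center), "radius": g.radius, "margin": g.margin
            }
        return out

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return str(path)


def segment_nodes(
    ct: VolumeGrid,
    config: SegmentationConfig = SegmentationConfig(),
    record_masks: bool = False,
) -> tuple[LabelMask, StageTrace]:
    """Segment nodal structures in a specimen CT volume.

    Returns the labeled component mask (components numbered deterministically)
    and a :class:`StageTrace` of per-stage counts. With ``record_masks`` the
    trace also stores each stage's binary mask for inspection.
    """
    trace = StageTrace()
    model = fit_kmeans_1d(ct.values, config.clustering)
    trace.model_centroids = [float(c) for c in model.centroids]
    clusters = assign_clusters(ct, model)
    mask = extract_node_mask(clusters, model)
    trace.record("node_cluster", mask, config.connectivity_3d, record_masks)

    case = config.case
    if isinstance(case, str) and case == "auto":
        non_air = clusters.with_labels((clusters.labels >= 2).astype(np.int32))
        case = estimate_case_geometry(non_air, axis=config.slice_axis, margin=config.case_margin)
    if case is not None:
        trace.case_geometry = case
        mask = remove_case(mask, case)
    trace.record("case_removal", mask, config.connectivity_3d, record_masks)

    mask = erode(mask, StructuringElement(config.element_shape, config.erosion_radius))
    trace.record("erosion", mask, config.connectivity_3d, record_masks)

    mask = fill_holes(mask, slice_axis=config.slice_axis if config.fill_slicewise else None)
    trace.record("filling", mask, config.connectivity_3d, record_masks)

    mask = filter_small_2d(mask, config.min_pixels_2d, config.slice_axis, config.connectivity_2d)
    trace.record("filter_2d", mask, config.connectivity_3d, record_masks)

    mask = dilate(mask, StructuringElement(config.element_shape, config.dilation_radius))
    trace.record("dilation", mask, config.connectivity_3d, record_masks)

    mask = filter_small_3d(mask, config.min_voxels_3d, config.connectivity_3d)
    trace.record("filter_3d", mask, config.connectivity_3d, record_masks)

    labeled = label_components(mask, config.connectivity_3d)
    return labeled, trace


def run_from_files(ct_path, config_path=None, out_mask_path=None, trace_path=None) -> StageTrace:
    """File-level composition: read CT, segment, write mask (and trace)."""
    from .config import load_config

    ct = vio.read_volume(ct_path)
    config = load_config(config_path) if config_path else SegmentationConfig()
    labeled, trace = segment_nodes(ct, config)
    if out_mask_path is not None:
        vio.write_mask(labeled, out_mask_path)
    if trace_path is not None:
        trace.to_json(trace_path)
    return trace
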