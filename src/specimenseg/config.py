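"""TOML configuration for the segmentation pipeline.

Every parameter the method leaves open (kernel radii, size thresholds,
connectivities, case geometry, clustering seeds) is visible and overridable
in one file, so a run's full parameterization is user-auditable. Unknown
keys are rejected with the offending key named.
"""

from __future__ import annotations

import tomllib

from .clustering import ClusteringConfig
from .morphology import CaseGeometry
from .pipeline import SegmentationConfig

__all__ = ["load_config", "parse_config", "DEFAULT_CONFIG_TOML"]

DEFAULT_CONFIG_TOML = """\
# specimenseg pipeline configuration (all values are the defaults)

[clustering]
k = 3            # air / fat / node tissue clusters
seed = 0
max_iter = 300
tol = 1e-6
n_init = 5       # k-means++ restarts, lowest inertia kept
subsample = 2000000  # voxel cap for the fit; assignment always covers all voxels

[case]
mode = "auto"    # "auto" | "fixed" | "none"
margin = 0.8     # mm stripped inside the (estimated or fixed) wall
# for mode = "fixed":
# axis = 2
# center = [0.0, 0.0]
# radius = 7.0

[morphology]
element_shape = "ball"
erosion_radius = 2
dilation_radius = 2
fill_slicewise = false
min_pixels_2d = 20
min_voxels_3d = 500
connectivity_2d = 8
connectivity_3d = 26
slice_axis = 2
"""

_CLUSTERING_KEYS = {"k", "seed", "max_iter", "tol", "n_init", "subsample"}
_CASE_KEYS = {"mode", "margin", "axis", "center", "radius"}
_MORPH_KEYS = {
    "element_shape",
    "erosion_radius",
    "dilation_radius",
    "fill_slicewise",
    "min_pixels_2d",
    "min_voxels_3d",
    "connectivity_2d",
    "connectivity_3d",
    "slice_axis",
}


def _check_keys(section: str, data: dict, allowed: set[str]):
    for key in data:
        if key not in allowed:
            raise ValueError(f"unknown config key [{section}] {key!r}; allowed: {sorted(allowed)}")


def parse_config(data: dict) -> SegmentationConfig:
    """Build a SegmentationConfig from a parsed TOML mapping."""
    for section in data:
        if section not in ("clustering", "case", "morphology"):
            raise ValueError(
                f"unknown config section {section!r}; allowed: clustering, case, morphology"
            )
    clus = dict(data.get("clustering", {}))
    _check_keys("clustering", clus, _CLUSTERING_KEYS)
    if clus.get("subsample", 1) in (0, -1, "none"):
        clus["subsample"] = None
    clustering = ClusteringConfig(**clus)

    case_sec = dict(data.get("case", {}))
    _check_keys("case", case_sec, _CASE_KEYS)
    mode = case_sec.pop("mode", "auto")
    margin = float(case_sec.pop("margin", 0.8))
    if mode == "auto":
        if case_sec:
            raise ValueError(f"[case] keys {sorted(case_sec)} only apply to mode = 'fixed'")
        case = "auto"
    elif mode == "none":
        case = None
    elif mode == "fixed":
        case = CaseGeometry(
            axis=int(case_sec.get("axis", 2)),
            center=tuple(case_sec.get("center", (0.0, 0.0))),
            radius=float(case_sec["radius"]),
            margin=margin,
        )
    else:
        raise ValueError(f"unknown [case] mode {mode!r}; use auto, fixed or none")

    morph = dict(data.get("morphology", {}))
    _check_keys("morphology", morph, _MORPH_KEYS)
    return SegmentationConfig(clustering=clustering, case=case, case_margin=margin, **morph)


def load_config(path) -> SegmentationConfig:
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ValueError(f"{path}: invalid TOML config: {exc}") from exc
    try:
        return parse_config(data)
    except (ValueError, TypeError, KeyError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
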