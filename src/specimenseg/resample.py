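"""Nearest-neighbor mask resampling between CT and PET grids.

The CT-based segmentation mask lives on the fine CT lattice (0.1 mm) and must
be moved onto the coarser PET lattice (0.4 mm), whose size, spacing and origin
all differ. Nearest-neighbor interpolation is mandatory for label images: it
can never introduce a label absent from the source. Because both grids are
axis-aligned, the nearest source voxel factorizes per axis, which keeps the
operation exact, fast and platform-deterministic (ties between two equidistant
source centers go to the lower source index).
"""

from __future__ import annotations

import warnings

import numpy as np

from .grid import Geometry, LabelMask

__all__ = ["resample_mask"]


def _nearest_indices(target: Geometry, source: Geometry, axis: int) -> np.ndarray:
    """Index of the source voxel center nearest each target center (tie -> lower)."""
    t = target.axis_coords(axis)
    f = (t - source.origin[axis]) / source.spacing[axis]
    # ceil(f - 1/2) rounds to nearest with exact halves going down
    return np.ceil(f - 0.5).astype(np.int64)


def resample_mask(mask: LabelMask, target: Geometry | LabelMask) -> LabelMask:
    """Resample a label mask onto ``target`` geometry by nearest neighbor.

    Each target voxel takes the label of the source voxel whose center is
    nearest to the target voxel's world center; target voxels whose nearest
    source center falls outside the source lattice become background. The
    output label set is always a subset of the input label set (plus 0).
    """
    tgt = target.geometry if isinstance(target, LabelMask) else target
    if not isinstance(tgt, Geometry):
        tgt = getattr(target, "geometry")
    src = mask.geometry
    if tgt.isclose(src):
        return LabelMask(mask.labels.copy(), tgt.spacing, tgt.origin)

    idx = [_nearest_indices(tgt, src, a) for a in range(3)]
    inside = [(ix >= 0) & (ix < src.shape[a]) for a, ix in enumerate(idx)]
    out = np.zeros(tgt.shape, dtype=mask.labels.dtype)
    if all(ins.any() for ins in inside):
        sel = [np.flatnonzero(ins) for ins in inside]
        gathered = mask.labels[np.ix_(*(ix[s] for ix, s in zip(idx, sel)))]
        out[np.ix_(*sel)] = gathered
    else:
        warnings.warn(
            "resample_mask: source and target grids do not overlap; returning an all-background mask",
            stacklevel=2,
        )
    result = LabelMask(out, tgt.spacing, tgt.origin)
    extra = result.label_set - mask.label_set - {0}
    assert not extra, f"nearest-neighbor resampling introduced new labels: {sorted(extra)}"
    return result
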