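"""NIfTI-1 reading and writing for volumes and label masks.

Only axis-aligned affines (translation + positive per-axis scaling) are
accepted; rotated or sheared headers are rejected loudly rather than silently
resampled, so the geometry contract stated in :mod:`specimenseg.grid` holds
for every object that enters the pipeline.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grid import LabelMask, VolumeGrid

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_OFFDIAG_TOL = 1e-6


def _snap(v: float) -> float:
    """Undo float32 truncation of header geometry.

    The NIfTI-1 affine is stored in float32 (~7.2 significant decimal
    digits); snapping to 7 significant digits recovers decimal spacings and
    origins (0.1 mm, 0.4 mm, ...) exactly.
    """
    return float(f"{float(v):.7g}")


def _grid_from_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, header declares {img.shape} (dim field)")
    affine = img.affine
    lin = affine[:3, :3]
    off = lin - np.diag(np.diag(lin))
    scale = max(1.0, float(np.abs(np.diag(lin)).max()))
    if np.abs(off).max() > _OFFDIAG_TOL * scale:
        raise ValueError(
            f"{path}: affine (srow/qform) is rotated or sheared; only axis-aligned grids are supported"
        )
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive spacing in affine diagonal (pixdim): {spacing}")
    origin = affine[:3, 3]
    return data, tuple(_snap(s) for s in spacing), tuple(_snap(o) for o in origin)


def read_volume(path) -> VolumeGrid:
    """Read a 3D scalar volume (CT or PET) from a NIfTI-1 file."""
    data, spacing, origin = _grid_from_nifti(path)
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def _affine(grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def write_volume(grid: VolumeGrid, path) -> str:
    """Write a volume as NIfTI-1; round-trips values and geometry exactly."""
    img = nib.Nifti1Image(grid.values, _affine(grid))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    return str(path)


def read_mask(path) -> LabelMask:
    """Read an integer label mask; non-integer voxel values are rejected."""
    data, spacing, origin = _grid_from_nifti(path)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.rint(data)):
            raise ValueError(f"{path}: mask contains non-integer voxel values")
        data = np.rint(data).astype(np.int64)
    if data.min(initial=0) < 0:
        raise ValueError(f"{path}: mask contains negative labels")
    return LabelMask(data.astype(np.int32), spacing, origin)


def write_mask(mask: LabelMask, path) -> str:
    """Write a label mask as NIfTI-1 (uint16 when labels fit, else uint32)."""
    mx = int(mask.labels.max(initial=0))
    dtype = np.uint16 if mx < np.iinfo(np.uint16).max else np.uint32
    img = nib.Nifti1Image(mask.labels.astype(dtype), _affine(mask))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
    return str(path)
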