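"""Physical-grid containers for volumes and label masks.

Every image in this package lives on an axis-aligned 3D lattice: the world
coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` in mm,
where ``origin`` addresses the *center* of voxel ``(0, 0, 0)``. No rotation or
shear is supported — the specimen imaging context gives no rotation semantics,
and keeping the mapping to a translation plus per-axis scaling makes geometry
contracts (resampling, radial case filtering) exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Geometry", "VolumeGrid", "LabelMask"]


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got shape {arr.shape}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class Geometry:
    """Lattice geometry: voxel counts, mm spacing, and world-mm origin.

    ``origin`` is the world coordinate of the center of voxel (0, 0, 0);
    indexing is 0-based throughout.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive voxel counts, got {self.shape}")
        spacing = _as_triple(self.spacing, "spacing")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive and finite, got {spacing}")
        origin = _as_triple(self.origin, "origin")
        if any(not np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_coords(self, index) -> np.ndarray:
        """World-mm coordinate(s) of voxel index/indices (broadcasting)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def isclose(self, other: "Geometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
        )


class _Gridded:
    """Shared geometry plumbing for VolumeGrid and LabelMask."""

    def __init__(self, array: np.ndarray, spacing, origin):
        if array.ndim != 3:
            raise ValueError(f"expected a 3D array, got {array.ndim} dimensions")
        self._geometry = Geometry(array.shape, _as_triple(spacing, "spacing"), _as_triple(origin, "origin"))

    @property
    def geometry(self) -> Geometry:
        return self._geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._geometry.shape

    @property
    def size(self) -> tuple[int, int, int]:
        return self._geometry.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self._geometry.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self._geometry.origin

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self._geometry.spacing))


class VolumeGrid(_Gridded):
    """A 3D scalar field (CT attenuation or PET SUV) on a physical grid.

    CT intensities are treated as abstract attenuation units, monotone with
    tissue density; no Hounsfield calibration is attempted because downstream
    clustering only needs the density ordering.
    """

    def __init__(self, values, spacing=1.0, origin=0.0):
        values = np.asarray(values, dtype=np.float64)
        super().__init__(values, spacing, origin)
        if not np.all(np.isfinite(values)):
            raise ValueError("volume values must all be finite")
        self.values = values

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing, self.origin)

    def __eq__(self, other):
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.geometry.isclose(other.geometry) and np.array_equal(self.values, other.values)


class LabelMask(_Gridded):
    """Integer-labeled lattice sharing VolumeGrid geometry; 0 = background."""

    def __init__(self, labels, spacing=1.0, origin=0.0):
        labels = np.asarray(labels)
        if labels.dtype == bool:
            labels = labels.astype(np.int32)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(np.isfinite(labels)) or not np.all(labels == np.rint(labels)):
                raise ValueError("mask labels must be integer-valued")
            labels = np.rint(labels).astype(np.int32)
        if labels.min(initial=0) < 0:
            raise ValueError("mask labels must be non-negative")
        super().__init__(labels, spacing, origin)
        self.labels = labels

    def with_labels(self, labels: np.ndarray) -> "LabelMask":
        return LabelMask(labels, self.spacing, self.origin)

    @property
    def label_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels))

    def as_bool(self) -> np.ndarray:
        return self.labels > 0

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def __eq__(self, other):
        if not isinstance(other, LabelMask):
            return NotImplemented
        return self.geometry.isclose(other.geometry) and np.array_equal(self.labels, other.labels)
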