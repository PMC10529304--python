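"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, BFS, per-voxel loops) and
shares no code with the package.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def kmeans_1d_optimal(values, k: int) -> tuple[float, list[list[float]]]:
    """Globally optimal 1-D k-means by exhaustive contiguous-partition search.

    Optimal 1-D k-means clusters are contiguous intervals of the sorted data,
    so enumerating the C(n-1, k-1) cut placements finds the global optimum.
    Returns (minimal SSE, the optimal groups).
    """
    x = sorted(float(v) for v in values)
    n = len(x)
    best = (float("inf"), None)
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = 0.0
        groups = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = x[lo:hi]
            mu = sum(seg) / len(seg)
            sse += sum((v - mu) ** 2 for v in seg)
            groups.append(seg)
        if sse < best[0]:
            best = (sse, groups)
    return best


_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: None,
    26: None,
}


def _neighbor_offsets(connectivity: int):
    if connectivity == 6:
        return _OFFSETS[6]
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 18 and order == 3:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """BFS connected-component labeling, numbered by raster-order discovery."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    offsets = _neighbor_offsets(connectivity)
    next_label = 0
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k] and out[i, j, k] == 0:
                    next_label += 1
                    queue = deque([(i, j, k)])
                    out[i, j, k] = next_label
                    while queue:
                        a, b, c = queue.popleft()
                        for dx, dy, dz in offsets:
                            p, q, r = a + dx, b + dy, c + dz
                            if 0 <= p < nx and 0 <= q < ny and 0 <= r < nz:
                                if mask[p, q, r] and out[p, q, r] == 0:
                                    out[p, q, r] = next_label
                                    queue.append((p, q, r))
    return out


def nearest_neighbor_resample(src: np.ndarray, src_spacing, src_origin, tgt_shape, tgt_spacing, tgt_origin) -> np.ndarray:
    """Per-voxel nearest-source-center lookup in world coordinates (tie -> lower index)."""
    src = np.asarray(src)
    out = np.zeros(tgt_shape, dtype=src.dtype)
    for i in range(tgt_shape[0]):
        for j in range(tgt_shape[1]):
            for k in range(tgt_shape[2]):
                idx = []
                ok = True
                for axis, t in enumerate((i, j, k)):
                    w = tgt_origin[axis] + t * tgt_spacing[axis]
                    centers = src_origin[axis] + np.arange(src.shape[axis]) * src_spacing[axis]
                    if w < centers[0] - src_spacing[axis] / 2 or w >= centers[-1] + src_spacing[axis] / 2:
                        ok = False  # outside the source lattice extent
                        break
                    d = np.abs(centers - w)
                    best = int(np.flatnonzero(d == d.min())[0])  # lowest index on ties
                    idx.append(best)
                if ok:
                    out[i, j, k] = src[tuple(idx)]
    return out


def confusion_loop(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) by an explicit voxel loop."""
    tp = tn = fp = fn = 0
    for p, t in zip(np.asarray(pred).astype(bool).ravel(), np.asarray(truth).astype(bool).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn
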