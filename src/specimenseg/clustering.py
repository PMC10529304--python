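"""1-D k-means tissue clustering of CT attenuation values.

The specimen scene contains three density-ordered tissue classes — air, fat,
and soft tissue (lymph nodes plus adjacent vessels/fibrotic tissue) — so a
k = 3 Lloyd clustering of the one-dimensional attenuation histogram separates
them without any training data. Clusters are mapped to tissue roles strictly
by ascending centroid value (air < fat < node), which is fixed by physics,
and the node-cluster voxels form the initial binary segmentation mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .grid import LabelMask, VolumeGrid

__all__ = ["ClusteringConfig", "ClusterModel", "fit_kmeans_1d", "assign_clusters", "extract_node_mask"]

#: tissue roles by ascending centroid rank for the k = 3 model
TISSUE_ROLES_K3 = {0: "air", 1: "fat", 2: "node"}


@dataclass(frozen=True)
class ClusteringConfig:
    """Parameters of the 1-D k-means fit.

    ``subsample`` caps the number of voxels used for fitting (full volumes at
    1024x1024x512 need not all enter Lloyd iterations); assignment afterwards
    always covers every voxel. ``n_init`` k-means++ restarts keep the lowest
    inertia, making the fit deterministic under ``seed``.
    """

    k: int = 3
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-6
    n_init: int = 5
    subsample: int | None = 2_000_000

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValueError(f"tol must be >= 0, got {self.tol}")
        if self.n_init < 1:
            raise ValueError(f"n_init must be >= 1, got {self.n_init}")


@dataclass(frozen=True)
class ClusterModel:
    """Fitted 1-D k-means model: ascending centroids and converged inertia."""

    centroids: np.ndarray
    inertia: float

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("centroids must be a non-empty 1-D array")
        if not np.all(np.diff(c) > 0):
            raise ValueError(f"centroids must be strictly increasing, got {c}")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")
        object.__setattr__(self, "centroids", c)

    @property
    def k(self) -> int:
        return int(self.centroids.size)

    @property
    def tissue_roles(self) -> dict[int, str]:
        if self.k == 3:
            return dict(TISSUE_ROLES_K3)
        return {i: f"cluster_{i}" for i in range(self.k)}

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Nearest-centroid labels 0..k-1; equidistant values go to the lower centroid."""
        mids = (self.centroids[:-1] + self.centroids[1:]) / 2.0
        # side='left': a value exactly at a midpoint counts zero midpoints as
        # strictly below it, i.e. the tie goes to the lower cluster.
        return np.searchsorted(mids, np.asarray(values, dtype=float), side="left")


def _exact_kmeans_1d(x: np.ndarray, k: int) -> ClusterModel:
    """Globally optimal 1-D k-means by dynamic programming over the sorted sample.

    Optimal 1-D k-means clusters are contiguous intervals of the sorted data,
    so the optimum is computable exactly (Ckmeans.1d.dp); duplicates are
    collapsed into weights, making the cost O(k * n_distinct^2).
    """
    v, w = np.unique(x, return_counts=True)
    n = v.size
    w = w.astype(np.float64)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs = np.concatenate([[0.0], np.cumsum(w * v)])
    cq = np.concatenate([[0.0], np.cumsum(w * v * v)])

    def seg_sse(i, j):
        """Weighted SSE of v[i..j] (i may be an array, j scalar)."""
        tw = cw[j + 1] - cw[i]
        ts = cs[j + 1] - cs[i]
        return (cq[j + 1] - cq[i]) - ts * ts / tw

    cost = np.full((k, n), np.inf)
    cut = np.zeros((k, n), dtype=np.int64)
    cost[0] = cq[1:] - cs[1:] ** 2 / cw[1:]  # SSE of the prefix v[0..j]
    for m in range(1, k):
        for j in range(m, n):
            i = np.arange(m, j + 1)
            cand = cost[m - 1][i - 1] + seg_sse(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            cut[m, j] = i[best]
    bounds = [n]
    j = n - 1
    for m in range(k - 1, 0, -1):
        j = int(cut[m, j]) - 1
        bounds.append(j + 1)
    bounds.append(0)
    bounds = bounds[::-1]
    centroids = np.array(
        [(cs[b1] - cs[b0]) / (cw[b1] - cw[b0]) for b0, b1 in zip(bounds[:-1], bounds[1:])]
    )
    return ClusterModel(centroids=centroids, inertia=float(max(cost[k - 1, n - 1], 0.0)))


#: largest distinct-value count for which the exact DP solver is used
_EXACT_MAX_DISTINCT = 2048


def fit_kmeans_1d(values, config: ClusteringConfig = ClusteringConfig()) -> ClusterModel:
    """Fit 1-D k-means to a sample of attenuation values.

    When the sample's distinct-value alphabet is small the globally optimal
    contiguous partition is computed exactly by dynamic programming; larger
    continuous samples use Lloyd's algorithm with k-means++ restarts plus one
    deterministic even-spread start, keeping the lowest inertia. Raises
    ``ValueError`` when the sample holds fewer than ``k`` distinct values.
    Centroids are returned in ascending order; the inertia is the
    within-cluster sum of squared deviations over the (sub)sample the fit saw.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot cluster an empty sample")
    n_distinct = np.unique(x).size
    if n_distinct < config.k:
        raise ValueError(
            f"need at least k={config.k} distinct attenuation values, sample has {n_distinct}"
        )
    if config.subsample is not None and x.size > config.subsample:
        rng = np.random.default_rng(config.seed)
        x = rng.choice(x, size=config.subsample, replace=False)
        if np.unique(x).size < config.k:  # pathological subsample; fall back to full data
            x = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(x).size <= _EXACT_MAX_DISTINCT:
        return _exact_kmeans_1d(x, config.k)
    common = dict(
        n_clusters=config.k,
        max_iter=config.max_iter,
        tol=config.tol,
        algorithm="lloyd",
    )
    km = KMeans(
        init="k-means++", n_init=config.n_init, random_state=config.seed, **common
    ).fit(x[:, None])
    best = km
    # one extra Lloyd restart from evenly spread seeds over the data range:
    # k-means++ seeds proportionally to squared distance, which on strongly
    # imbalanced 1-D mixtures can leave a minority mode without a seed in
    # every restart; the deterministic spread start covers that basin
    spread = np.linspace(x.min(), x.max(), config.k)[:, None]
    if np.unique(spread).size == config.k:
        km2 = KMeans(init=spread, n_init=1, random_state=config.seed, **common).fit(x[:, None])
        if km2.inertia_ < best.inertia_:
            best = km2
    order = np.argsort(best.cluster_centers_.ravel())
    centroids = best.cluster_centers_.ravel()[order]
    return ClusterModel(centroids=centroids, inertia=float(best.inertia_))


def assign_clusters(ct: VolumeGrid, model: ClusterModel) -> LabelMask:
    """Label every voxel 1..k by nearest centroid (ties to the lower centroid)."""
    labels = model.predict(ct.values) + 1
    return LabelMask(labels.astype(np.int32), ct.spacing, ct.origin)


def extract_node_mask(cluster_mask: LabelMask, model: ClusterModel) -> LabelMask:
    """Binary mask of the node (highest-density) cluster.

    The fat cluster is merged into the air background, leaving a two-level
    mask of the nodal cluster. Only the k = 3 air/fat/node model is supported.
    """
    if model.k != 3:
        raise ValueError(f"node-mask extraction requires the k=3 air/fat/node model, got k={model.k}")
    binary = (cluster_mask.labels == model.k).astype(np.int32)
    return cluster_mask.with_labels(binary)
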