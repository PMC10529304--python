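"""Synthetic specimen PET/CT phantom with voxel-level ground truth.

The generator emulates the scene the segmentation method assumes: a resected
lymph-nodal specimen lying in a cylindrical container filled with fatty
tissue, imaged ex vivo on a high-resolution PET/CT specimen scanner. The CT
volume contains four density-ordered tissue classes (air exterior and
container lumen gaps < hilum < fat < soft-tissue nodes, plus a denser
container wall); the paired PET volume, on its own coarser grid, carries
elevated tracer uptake inside the nodes over a uniform specimen background.

Optional difficulty features mirror the failure modes discussed for real
specimens: low-density hila inside nodes (excluded by density clustering,
recoverable only by hole-filling), and thin vessel bridges touching nodes
(wrongly connected at clustering, detachable only by erosion).

CT intensities are arbitrary attenuation units mirroring CT-like ordering;
only the ordering matters to the method. All randomness flows from a single
seed through per-purpose generator streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import Geometry, LabelMask, VolumeGrid
from .morphology import CaseGeometry

__all__ = ["PhantomSpec", "generate_phantom", "perturb"]

_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic specimen.

    Defaults are the test-scale study conditions: a 160^3 CT grid at 0.1 mm
    (16 mm cube, matching the scanner's CT voxel size), PET at 0.4 mm, three
    well-separated ellipsoidal nodes of 1.5-2.5 mm semi-axes, and high
    fat/node contrast relative to the CT noise. Sizes up to 1024x1024x512
    are accepted for stress runs.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: float = 0.1  # mm, CT grid

    # container: cylinder along z centered on the grid center
    case_radius: float = 7.0  # mm, outer wall radius
    case_wall: float = 0.2  # mm, visible wall thickness in CT
    case_intensity: float = 200.0

    # tissue means in attenuation units, ordered air < hilum <= fat < node
    air: float = -1000.0
    hilum: float = -300.0
    fat: float = -100.0
    vessel: float = 30.0
    node: float = 40.0
    ct_noise_sd: float = 20.0  # white-noise amplitude before reconstruction smoothing
    ct_noise_smooth_vox: float = 1.0  # Gaussian sigma (voxels) of the reconstruction correlation

    n_nodes: int = 3
    node_semiaxes_mm: tuple[float, float] = (1.5, 2.5)
    min_separation_mm: float = 2.0  # surface-to-surface gap (bounding spheres)
    node_inset_mm: float = 1.0  # clearance kept between nodes and the case lumen

    hilum_enabled: bool = False
    hilum_rel_size: float = 0.35  # hilum semi-axes as a fraction of the node's

    n_vessel_bridges: int = 0
    vessel_radius_mm: float = 0.2
    vessel_length_mm: float = 2.0

    pet_background: float = 1.5  # SUV
    pet_peak: float = 8.0  # SUV at each node center
    pet_noise_rel: float = 0.05  # relative sd, clipped at 3 sd
    pet_spacing: float = 0.4  # mm

    seed: int = 0

    def __post_init__(self):
        if not (self.air < self.hilum <= self.fat < self.node):
            raise ValueError(
                "tissue intensities must satisfy air < hilum <= fat < node, got "
                f"air={self.air}, hilum={self.hilum}, fat={self.fat}, node={self.node}"
            )
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        lo, hi = self.node_semiaxes_mm
        if not (0 < lo <= hi):
            raise ValueError(f"node semi-axis range must be positive and ordered, got {self.node_semiaxes_mm}")
        if self.case_wall <= 0 or self.case_radius <= self.case_wall:
            raise ValueError("case must satisfy 0 < wall < radius")
        if self.pet_peak <= self.pet_background:
            raise ValueError("node uptake peak must exceed the background uptake")
        if not (0 < self.hilum_rel_size < 0.7):
            raise ValueError("hilum_rel_size must lie in (0, 0.7) so the hilum stays inside the node")

    @property
    def ct_geometry(self) -> Geometry:
        origin = tuple(-(n - 1) / 2.0 * self.spacing for n in self.shape)
        return Geometry(self.shape, (self.spacing,) * 3, origin)

    @property
    def pet_geometry(self) -> Geometry:
        shape = tuple(max(1, int(round(n * self.spacing / self.pet_spacing))) for n in self.shape)
        origin = tuple(-(n - 1) / 2.0 * self.pet_spacing for n in shape)
        return Geometry(shape, (self.pet_spacing,) * 3, origin)

    @property
    def case_geometry(self) -> CaseGeometry:
        return CaseGeometry(axis=2, center=(0.0, 0.0), radius=self.case_radius, margin=0.0)


def _axis_grids(geom: Geometry):
    return [geom.axis_coords(a).reshape([-1 if i == a else 1 for i in range(3)]) for a in range(3)]


def _place_nodes(spec: PhantomSpec, ss: np.random.SeedSequence):
    """Rejection-sample node centers and semi-axes; deterministic per node index."""
    lo, hi = spec.node_semiaxes_mm
    interior = spec.case_radius - spec.case_wall
    half_z = (spec.shape[2] - 1) / 2.0 * spec.spacing
    nodes = []
    for i in range(spec.n_nodes):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(1, i)))
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            axes = rng.uniform(lo, hi, size=3)
            rmax = float(axes.max())
            rad_limit = interior - rmax - spec.node_inset_mm
            z_limit = half_z - rmax - spec.node_inset_mm
            if rad_limit <= 0 or z_limit <= 0:
                continue
            cx, cy = rng.uniform(-rad_limit, rad_limit, size=2)
            if cx * cx + cy * cy > rad_limit * rad_limit:
                continue
            cz = rng.uniform(-z_limit, z_limit)
            center = np.array([cx, cy, cz])
            ok = all(
                np.linalg.norm(center - c2) >= rmax + r2 + spec.min_separation_mm
                for c2, r2 in ((n["center"], n["rmax"]) for n in nodes)
            )
            if ok:
                nodes.append({"center": center, "axes": axes, "rmax": rmax, "label": i + 1})
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"infeasible packing: could not place node {i + 1}/{spec.n_nodes} after "
                f"{_PLACEMENT_ATTEMPTS} attempts (container too small for the requested "
                "node sizes and separation)"
            )
    return nodes


def _ellipsoid_region(geom: Geometry, center, axes):
    """Bounding-box slices and the normalized squared ellipsoid distance within."""
    sl = []
    for a in range(3):
        coords = geom.axis_coords(a)
        lo = int(np.searchsorted(coords, center[a] - axes[a] - geom.spacing[a]))
        hi = int(np.searchsorted(coords, center[a] + axes[a] + geom.spacing[a]))
        sl.append(slice(max(lo, 0), min(hi + 1, geom.shape[a])))
    local = [
        ((geom.axis_coords(a)[sl[a]] - center[a]) / axes[a]).reshape([-1 if i == a else 1 for i in range(3)])
        for a in range(3)
    ]
    rho2 = local[0] ** 2 + local[1] ** 2 + local[2] ** 2
    return tuple(sl), rho2


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Generate (ct, pet, truth, meta) for a phantom specification.

    ``truth`` labels nodes 1..n on the CT grid (hilum voxels carry the node
    label); ``meta`` records placements and the container geometry. Outputs
    are bit-identical for identical specs.
    """
    geom = spec.ct_geometry
    X, Y, _ = _axis_grids(geom)
    r2 = X**2 + Y**2  # broadcastable (nx, ny, 1) radial distance from the z axis

    ct = np.full(spec.shape, spec.air, dtype=np.float64)
    interior = r2 < (spec.case_radius - spec.case_wall) ** 2
    shell = (r2 >= (spec.case_radius - spec.case_wall) ** 2) & (r2 < spec.case_radius**2)
    ct += interior * (spec.fat - spec.air)
    ct += shell * (spec.case_intensity - spec.air)

    nodes = _place_nodes(spec, np.random.SeedSequence(int(spec.seed)))
    truth = np.zeros(spec.shape, dtype=np.int32)
    for nd in nodes:
        sl, rho2 = _ellipsoid_region(geom, nd["center"], nd["axes"])
        inside = rho2 <= 1.0
        ct[sl][inside] = spec.node
        truth[sl][inside] = nd["label"]
        if spec.hilum_enabled:
            h_axes = nd["axes"] * spec.hilum_rel_size
            h_center = nd["center"] + np.array([0.3, 0.0, 0.0]) * nd["axes"]
            hsl, hrho2 = _ellipsoid_region(geom, h_center, h_axes)
            ct[hsl][hrho2 <= 1.0] = spec.hilum
            # truth keeps the node label over the hilum: it is part of the node

    for b in range(spec.n_vessel_bridges):
        nd = nodes[b % len(nodes)] if nodes else None
        if nd is None:
            break
        _paint_vessel(spec, geom, ct, nd, bridge_index=b)

    noise_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(2,)))
    if spec.ct_noise_sd > 0:
        noise = noise_rng.normal(0.0, spec.ct_noise_sd, size=spec.shape)
        if spec.ct_noise_smooth_vox > 0:
            # tomographic reconstruction noise is spatially correlated, not
            # voxel-wise white; smoothing the white field emulates that and
            # lowers the per-voxel sd accordingly
            from scipy.ndimage import gaussian_filter

            noise = gaussian_filter(noise, sigma=spec.ct_noise_smooth_vox)
        ct += noise

    pet = _generate_pet(spec, nodes)

    meta = {
        "seed": int(spec.seed),
        "case": {"axis": 2, "center": [0.0, 0.0], "radius": spec.case_radius, "wall": spec.case_wall},
        "nodes": [
            {
                "label": int(nd["label"]),
                "center_mm": [float(v) for v in nd["center"]],
                "semiaxes_mm": [float(v) for v in nd["axes"]],
            }
            for nd in nodes
        ],
    }
    ct_grid = VolumeGrid(ct, geom.spacing, geom.origin)
    truth_mask = LabelMask(truth, geom.spacing, geom.origin)
    return ct_grid, pet, truth_mask, meta


def _paint_vessel(spec: PhantomSpec, geom: Geometry, ct: np.ndarray, nd: dict, bridge_index: int):
    """A thin tube of soft-tissue density touching the node, pointing inward along x."""
    center = nd["center"]
    direction = -1.0 if center[0] > 0 else 1.0
    a = nd["axes"][0]
    x0 = center[0] + direction * (a - 2 * spec.spacing)  # start just inside the node surface
    x1 = x0 + direction * (a - a + spec.vessel_length_mm + 2 * spec.spacing)
    xs = geom.axis_coords(0)
    lo, hi = sorted((x0, x1))
    xsel = (xs >= lo) & (xs <= hi)
    ys = geom.axis_coords(1) - center[1]
    zs = geom.axis_coords(2) - center[2]
    rad2 = ys.reshape(1, -1, 1) ** 2 + zs.reshape(1, 1, -1) ** 2
    tube = xsel.reshape(-1, 1, 1) & (rad2 <= spec.vessel_radius_mm**2)
    ct[tube] = spec.vessel


def _generate_pet(spec: PhantomSpec, nodes) -> VolumeGrid:
    geom = spec.pet_geometry
    X, Y, _ = _axis_grids(geom)
    r2 = X**2 + Y**2
    pet = np.zeros(geom.shape, dtype=np.float64)
    interior = (r2 < (spec.case_radius - spec.case_wall) ** 2) & np.ones(geom.shape, dtype=bool)
    pet[interior] = spec.pet_background

    # smooth truncated-Gaussian uptake inside each node, peaking at the center
    sigma_rho = 0.4
    for nd in nodes:
        sl, rho2 = _ellipsoid_region(geom, nd["center"], nd["axes"])
        inside = rho2 <= 1.0
        profile = spec.pet_background + (spec.pet_peak - spec.pet_background) * np.exp(
            -rho2 / (2 * sigma_rho**2)
        )
        region = pet[sl]
        region[inside] = profile[inside]
        pet[sl] = region

    if spec.pet_noise_rel > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(3,)))
        rel = np.clip(
            rng.normal(0.0, spec.pet_noise_rel, size=geom.shape),
            -3 * spec.pet_noise_rel,
            3 * spec.pet_noise_rel,
        )
        pet *= 1.0 + rel

    # the configured peak is exact: clip node voxels at the peak and pin the
    # voxel nearest each node center to it, so SUVmax is analytic
    for nd in nodes:
        sl, rho2 = _ellipsoid_region(geom, nd["center"], nd["axes"])
        region = pet[sl]
        inside = rho2 <= 1.0
        region[inside] = np.minimum(region[inside], spec.pet_peak)
        pet[sl] = region
        idx = tuple(
            int(np.clip(round((nd["center"][a] - geom.origin[a]) / geom.spacing[a]), 0, geom.shape[a] - 1))
            for a in range(3)
        )
        pet[idx] = spec.pet_peak

    return VolumeGrid(pet, geom.spacing, geom.origin)


def perturb(spec: PhantomSpec, dimension: str) -> list[PhantomSpec]:
    """A deterministic family of specs sweeping one difficulty dimension.

    ``noise`` sweeps the CT noise sd; ``density`` narrows the fat-node
    contrast and enables hila (heterogeneous, harder-to-cluster nodes);
    ``overlap`` tightens node separation while adding vessel bridges.
    """
    if dimension == "noise":
        return [dataclasses.replace(spec, ct_noise_sd=sd) for sd in (5.0, 20.0, 50.0)]
    if dimension == "density":
        steps = [
            {"node": 40.0, "vessel": 30.0, "hilum_enabled": False},
            {"node": -10.0, "vessel": -15.0, "hilum_enabled": True},
            {"node": -40.0, "vessel": -45.0, "hilum_enabled": True},
        ]
        return [dataclasses.replace(spec, **s) for s in steps]
    if dimension == "overlap":
        steps = [
            {"min_separation_mm": 2.0, "n_vessel_bridges": 0},
            {"min_separation_mm": 1.0, "n_vessel_bridges": 2},
            {"min_separation_mm": 0.5, "n_vessel_bridges": 4},
        ]
        return [dataclasses.replace(spec, **s) for s in steps]
    raise ValueError(f"unknown difficulty dimension {dimension!r}; use noise, density or overlap")
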