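# Methods

## Scope and model

`specimenseg` segments lymph-nodal structures in ex vivo specimen CT volumes
by unsupervised tissue clustering plus binary morphology, and applies the
resulting masks to the paired PET volume for semi-quantification. The method
assumes the simplified anatomy of a resected specimen in a container: a small
number of density-ordered tissue classes (air, fat, soft tissue), an
axis-aligned grid with no rotation, and nodes that are compact soft-tissue
bodies possibly touching thin vessels or fibrotic strands.

## Geometry conventions

All images live on axis-aligned lattices; the world coordinate of voxel
(i, j, k) is `origin + (i, j, k) * spacing` (mm), with `origin` at the
*center* of voxel (0, 0, 0) and 0-based indexing. NIfTI-1 is the on-disk
format; rotated or sheared affines are rejected rather than silently
resampled. The NIfTI-1 affine is stored in float32, so spacings/origins are
snapped to 7 significant decimal digits on read — decimal grids (0.1 mm CT,
0.4 mm PET) round-trip exactly; geometry needing more than 7 significant
digits cannot be represented in the format.

CT intensities are treated as abstract attenuation units monotone with
density. Only the ordering air < fat < soft tissue enters the method, so no
Hounsfield calibration is attempted.

## Clustering

A k = 3 clustering of the scalar attenuation sample separates air, fat and
the soft-tissue (node) class; cluster → tissue assignment is strictly by
ascending centroid, which is fixed by physics. Two solvers sit behind
`fit_kmeans_1d`:

- **Exact (small alphabets).** Optimal 1-D k-means clusters are contiguous
  intervals of the sorted sample, so when the sample has ≤ 2048 distinct
  values the global optimum is computed by weighted dynamic programming
  (the Ckmeans.1d.dp algorithm). This is exact and deterministic.
- **Lloyd (large continuous samples).** k-means++ with `n_init = 5` restarts
  (seeded, lowest inertia kept) plus one deterministic start with centroids
  spread evenly over the data range. The extra start matters: k-means++
  seeds proportionally to squared distance, and on strongly imbalanced 1-D
  mixtures (a small soft-tissue mode next to a populous container-wall mode)
  every random restart can leave the minority mode unseeded, converging to a
  visibly worse partition. The spread start covers that basin; the lowest
  inertia of all starts is kept, so it can only help.

Fitting may run on a uniform random subsample (default cap 2 × 10⁶ voxels,
seeded); assignment always covers every voxel, by nearest centroid with ties
going to the lower centroid (determinism). Volumes with fewer than k
distinct values are rejected as unsegmentable rather than guessed at.

## Morphology and parameter defaults

The stage order is fixed: clustering → fat-cluster removal → case removal →
erosion → hole-filling → 2D small-feature removal → dilation → 3D
small-component removal → component labeling. Erosion runs before filling so
detached noise cannot seal cavities; dilation compensates erosion with an
equal-radius element.

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| structuring element | ball, radius 2 | voxels | isotropic; equal radii so dilation compensates erosion |
| hole filling | 3D | — | a node hilum is a 3D cavity; per-slice filling available as a switch |
| `min_pixels_2d` | 20 | pixels/slice | ≈ 0.2 mm² at 0.1 mm spacing; well below any node cross-section |
| `min_voxels_3d` | 500 | voxels | ≈ 0.5 mm³; two orders below the smallest plausible node |
| connectivity | 8 (2D), 26 (3D) | — | standard defaults; configurable |
| case margin | 0.8 | mm | strips the wall plus partial-volume rim inside the estimated radius |

The container («case») is removed by zeroing voxels whose radial world
distance from the cylinder axis exceeds `radius − margin`. The geometry can
be given explicitly or estimated as the smallest enclosing cylinder of the
non-air support (planar centroid axis, maximal radial extent plus half a
voxel diagonal); the estimator is best-effort and always overridable.

Component labels are assigned in lexicographic order of each component's
minimal voxel index, making labeling reproducible across platforms
independent of the labeling library's internal order.

## Resampling and quantification

Masks move from the CT grid to the PET grid by nearest-neighbor lookup: each
target voxel takes the label of the source voxel whose center is nearest in
world coordinates, ties to the lower source index, out-of-lattice targets to
background. Per axis the lookup factorizes (both grids are axis-aligned), so
the operation is exact and fast even at 1024 × 1024 × 512 → 252 × 252 × 152.
The output label set is asserted to be a subset of the input's on every call.

SUVmax is the maximum PET value over a label; TBR divides it by a background
SUVmax taken either over a user ROI or, by default, over everything outside
the node mask dilated by a 1 mm guard band (against uptake spill-over at
node boundaries). TBR is reported rounded half-away-from-zero to one decimal
and retained at full precision internally. `suv_scale` converts activity
concentration (Bq/mL) to body-weight SUV for volumes not already in SUV
units; decay correction is assumed done by the scanner.

## Evaluation

Predicted components are attributed to reference nodes by maximal voxel
overlap (ties to the lower reference label); each reference class is then
scored voxel-wise over the full field of view against the union of its
matched components. Undefined quotients (0/0) are reported as absent (NaN),
never as zero. Aggregates: micro pools confusion counts (predicted
components matching no reference node enter the pooled counts once, as a
dedicated false-positive pool), macro averages classes equally, weighted
averages by reference-voxel support. Counting true negatives over the whole
scanned volume (including air) intentionally reproduces the accuracy
inflation caused by class imbalance; Dice and Jaccard are the informative
overlap measures, related by D = 2J/(1+J) exactly.

## The phantom generator

The generator emulates the study conditions end-to-end, with ground truth:

- **Scene.** A cylindrical case (default outer radius 7 mm, 0.2 mm visible
  wall at +200 units) filled with fat (−100) against an air exterior
  (−1000); 3 axis-aligned ellipsoidal nodes (+40) with semi-axes sampled in
  1.5–2.5 mm, ≥ 2 mm surface separation and ≥ 1 mm clearance from the case
  lumen, placed by seeded rejection sampling (bounded attempts, per-node RNG
  streams). Difficulty features: a low-density hilum (−300) inside each node
  (truth keeps hilum voxels in the node label — recovery requires
  hole-filling) and thin vessel bridges (+30) touching nodes (detachment
  requires erosion).
- **CT noise.** White Gaussian noise (sd 20 units) smoothed with a Gaussian
  of σ = 1 voxel. Tomographic reconstruction noise is spatially correlated,
  not voxel-wise white; unsmoothed iid noise at 0.1 mm voxels would produce
  salt-and-pepper cluster masks that no morphology-based pipeline could
  survive and that real reconstructions do not show. `ct_noise_sd` remains
  the difficulty dial.
- **PET.** Its own coarser grid (0.4 mm, center-aligned). Background uptake
  1.5 SUV inside the case lumen, truncated-Gaussian radial uptake inside
  each node peaking at 8.0 SUV at the center; 5 % relative noise clipped at
  3 sd, with node values clipped at the peak and the center voxel pinned to
  it, so SUVmax is analytic (exactly the configured peak) and background
  SUVmax is bounded by the clip.
- **Sweeps.** `perturb` generates one-dimensional difficulty families:
  `noise` (sd 5/20/50), `density` (fat–node contrast 140 → 90 → 60 units
  with hila enabled from the second step), `overlap` (separation
  2/1/0.5 mm with 0/2/4 vessel bridges).

Two generator choices deserve emphasis. First, the visible wall is thin
(0.2 mm) so that the globally optimal k = 3 partition groups the wall with
the nodes — the regime the method is designed for, in which the case is
removed geometrically afterwards. A high-density wall with a large voxel
population makes the optimal partition flip to merging nodes into fat, and
the pipeline then finds nothing; the same flip happens when node volume is
tiny relative to the wall, which is why the class-imbalance validation scene
uses a lower-density container (+120). This bistability is a real limitation
of 3-cluster density clustering in a 4-mode scene, not an artifact. Second,
nodes are axis-aligned ellipsoids with piecewise-constant intensity — real
nodes are irregular and heterogeneous, which is precisely where recall
degrades; the `density` sweep probes that direction but passing tests on the
easy phantom do not certify performance on irregular real specimens.

## Problem sizes

Tests and the acceptance script run the phantom study at 160³ CT voxels
(16 mm field of view) with a 40³ PET grid, smaller auxiliary phantoms at
96³/64³, and the resampling contract additionally at the full scanner scale
(1024 × 1024 × 512 → 252 × 252 × 152). Segmentation of a 160³ volume takes
a few seconds on one CPU; clustering subsamples at 2 × 10⁶ voxels.

## Numerical choices

- Equidistant-value ties: to the lower centroid (clustering) and the lower
  source index (resampling) — platform-determinism.
- Report rounding: half-away-from-zero (2 decimals for metrics, 1 for TBR);
  full precision retained internally.
- Empty final mask is a result ("no nodes found"), not an error; an
  operating-room tool must distinguish that from failure.
- All RNG flows from explicit seeds through named `SeedSequence` streams;
  identical inputs and seeds give bit-identical outputs, including gzip
  (deterministic mtime).

## Known limitations

- No projection/reconstruction physics (no attenuation, scatter, ISRA/OSEM);
  the phantom models the *reconstructed* image statistics only.
- The 3-cluster model cannot represent scenes whose density histogram has
  more than three dominant modes (see the wall bistability above); a fixed
  k = 3 is a modeling commitment, not a fitted choice.
- Metrics quantify voxel overlap for segmented structures; they say nothing
  about the detection rate of pathological nodes.
- Background-SUVmax "non-target region" selection is a convention (dilated
  complement or user ROI); absolute TBR values depend on it.
- DICOM ingestion, rotated grids, SUVmean/SUVpeak/MTV/TLG and radiomics are
  out of scope.
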