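# Methods

## Problem and model

Given an axial head-CT series, the package reconstructs the outer skin
surface as an unordered set of 3D points in world millimetres. The core
assumption is that skin (and soft tissue generally) occupies a fixed
Hounsfield band, −200 to +220 HU, while air lies far below and cortical bone
far above it; the skin surface is therefore the outer boundary of the
thresholded soft-tissue region in every slice. Rather than meshing the
volume (which interpolates), boundaries are traced per slice in all three
orthogonal planes and projected through the acquisition geometry, so every
output point corresponds to a traced boundary position in original data.
Processing three planes serves two purposes: redundancy (a slice corrupted
by equipment or anatomy can be discarded outright) and density (surface
patches nearly tangent to one slicing plane are sampled well by the other
two).

## Slice validity filtering

All filters operate on the binarized slice and judge the *largest* contour,
on the grounds that the head is the dominant structure in any slice that is
worth keeping. The chain, in order, with its tunable parameters
(`FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| `centroid_valid_box` | rows 0–90%, cols 10–90% | fractional image rectangle the candidate centroid must occupy |
| `solidity_threshold` | 0.88 | minimum area / convex-hull-area for large contours |
| `solidity_min_area_px` | 40 000 | contours at or below this area are not solidity-tested (strict `>` gate) |
| `area_delta_trigger` | 0.15 | relative area change vs. the previous accepted slice below which the four-direction check runs |
| `row_step` / `min_pixel_gap` | 4 / 4 | row-crossing scan stride and the column gap that makes a boundary pixel count |
| `crossings_per_row_trigger` / `bad_row_limit` | 4 / 4 | counted pixels that make a row "bad"; bad rows beyond the limit reject the slice |
| `equipment_regions` | bottom 12% full-width band | fractional rectangles in which any foreground rejects the slice |

Design choices where the procedure is genuinely underdetermined:

* **Centroid box and equipment regions** are heuristic by nature; the
  defaults are chosen so that a centred head passes in all three
  orientations while border-hugging equipment fails. They are fractional
  rectangles rather than pixel rectangles so one configuration serves every
  orientation and image size.
* **Four-direction trigger.** The check runs when the candidate's area is
  *consistent* with the previous accepted slice (relative change ≤ 0.15).
  A largest contour misidentified because a discontinuity carved away part
  of the head tends to keep a plausible area while failing to enclose the
  full region — the cardinal-ray scan then finds foreground outside it. The
  first slice of each orientation has no reference area and skips the
  check; the reference is carried only across accepted slices and reset
  between orientations. The scan is deliberately cardinal-only and has a
  documented diagonal blind spot (tested as such).
* **Row-crossing counting.** A boundary pixel counts when it lies at least
  `min_pixel_gap` columns from the previously *seen* boundary pixel in that
  row, so a contiguous tangent run counts once and a convex contour never
  exceeds two counts per row. Counting from the previously *counted* pixel
  instead would flag tangent rows of perfectly convex contours.
* **Pixel connection.** The first-row connection line is drawn in the
  topmost foreground row, and every contour point within half a pixel of
  that row is stripped before projection, so the synthetic segment never
  becomes surface. A consequence visible in the output is a one-to-two
  voxel indentation of the bounding box on that side of each slice stack.
* **Solidity** uses exact polygon geometry (shoelace area, convex hull) on
  the traced boundary, with ties at the area gate resolved by the strict
  inequality.
* Contour ordering (area descending, ties by topmost-then-leftmost start)
  makes every verdict deterministic.

Contours are traced at the 0.5 level between foreground and background
pixel centres (sub-pixel). This places the boundary half a voxel outside
the last in-band voxel centre — the expectation of where the true surface
crosses the sampling grid — and measurably halves the surface bias relative
to integer boundary pixels.

## Projection and fusion

Each slice records which world axes its image rows/columns traverse
(sagittal and coronal images carry the z axis along rows, reversed, so the
head is upright); projection is the exact affine inverse of that indexing,
with the slice index supplying the third coordinate. Round-trip error is at
machine precision, and all three clouds land in the axial world frame by
construction.

Fusion order: per-plane voxel downsampling (1 mm default, grid anchored at
the cloud minimum, occupied cells replaced by their centroid, output
independent of point order) — axial bounding box — clipping of
sagittal/coronal clouds to the closed box — union — second downsampling at
the same voxel — outlier removal (radius pass: ≥ 4 neighbours within 2 mm;
statistical pass: mean 20-NN distance ≤ global mean + 2 σ). The centroid
representative and the minimum-anchored grid phase are conventional choices
exposed as parameters. Running the pipeline at a second, finer voxel
(0.38 mm) reuses the same extraction pass; only the fusion stage is
repeated.

## Synthetic phantoms and what they do (not) show

The generator voxelizes nested ellipsoids (skin / skull / brain, HU 40 /
700 / 30 in air at −1000) on an anisotropic grid, membership decided at the
voxel centre — the same convention thresholding later applies. Artifacts
emulate the nuisance structures the filters target: a soft-tissue-HU table
slab below the head, high-HU scalp fiducials (radius 4 mm: out of band, so
they carve a void the contour routes around at ≥ the marker radius), an
air cavity that breaks the skin ring's closure, and an optional nose
protrusion. Volumes are written as genuine single-frame CT DICOM series
(signed 16-bit HU, slope 1 / intercept 0) so the production reader is
exercised; round-trip is bit-exact for integer HU.

In end-to-end fixtures the slab is offset laterally from the head midline,
like a one-sided headrest. A slab centred directly below the head sits on
the downward centroid ray of every axial slice and the four-direction
filter then (correctly) discards those slices wholesale; the offset
geometry instead exercises the two mechanisms the fusion stage relies on —
largest-contour selection ignoring the slab, and the axial bounding box
clipping slab-only sagittal/coronal contours.

The analytic outer surface makes accuracy exact to compute: the nearest
point on a triaxial ellipsoid has no closed form, so the Lagrange condition
`x_i = a_i² p_i / (a_i² + t)` is solved for its largest root by a clamped,
vectorised Newton iteration on a convex decreasing function (tolerance
1e-9 mm; a centre query returns the minor-axis vertex; deeply interior
on-axis points inside the evolute resolve to the on-axis critical point,
which is irrelevant for near-surface clouds). Ground-truth "models" are
dense Fibonacci-spiral samplings of that surface.

What phantom results do **not** show: real scans have noise texture,
reconstruction-kernel ringing, continuous HU gradients at the skin–air
interface, and irregular anatomy (ears, nostrils) that the idealized
ellipsoid lacks. Phantom accuracy numbers therefore bound discretization
and pipeline error, not clinical segmentation error; the filter chain's
rejection behaviour on real anatomy is exercised only in the shapes the
artifacts idealize.

## Evaluation procedures

* **Unique points**: a query point is unique iff no reference point lies
  within the closed 1 mm ball (k-d tree; anti-monotone in the radius).
* **ICP**: trimmed point-to-point ICP — nearest-neighbour correspondences,
  per-iteration retention of the closest 90% (farthest-point removal),
  closed-form orthogonal-Procrustes update, convergence when the RMS
  improves by < 1e-4 mm. The initial transform is an explicit input
  standing in for coarse manual alignment; an optional seeded cap on
  source points makes large registrations reproducible. Note that on
  (near-)spherical clouds the rotation is only pinned through exact point
  identity; subsampling an exactly overlapping sphere pair reintroduces
  the rotational gauge freedom of the sphere.
* **Coverage field**: one-sided GT→cloud nearest distances with a 1 mm
  flagging cutoff; an empty test cloud flags everything at infinite
  distance.

## Problem sizes

The full-scale evaluation phantom is a 60 mm-radius sphere on a
272 × 288 × 224 grid at 0.5 × 0.5 × 0.625 mm — the in-plane spacing and
slice thickness of a typical head protocol — processed as 784 slices and
yielding ~56 k (1 mm voxel) to ~205 k (0.38 mm) surface points. Unit and
property tests use a 45 mm sphere at 1 mm isotropic spacing. Brute-force
oracles (all-pairs distances, per-pixel loops, triple-loop voxel
membership) run at n ≤ 3000 points or 40³ voxels.

## Known limitations

Only axis-aligned, single-frame, single-series axial CT is read; oblique or
gantry-tilted series are rejected, not resampled. The filter chain's
parameters are static across slices and patients. Coverage holes remain
where whole slices are rejected in all three planes (complex anatomy in
every view) and along each slice stack's stripped connection row at the
cranial vertex.
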