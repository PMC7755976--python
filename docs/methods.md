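# Methods

## Imaging model

Each side view is a pinhole camera with skew, two radial (`k1, k2`) and
two tangential (`p1, p2`) distortion coefficients, and a rigid
world-to-camera transform `x_cam = R x_world + t`. The world frame is
right-handed with `+z` vertical and its origin at the base centre of
the reconstruction volume; pixel coordinates are `(u, v) = (column,
row)`, 0-based at the top-left pixel centre. These conventions are
shared by the renderer, the carver and the parameter files, and the
camera JSON schema (`phenovox-cameras-v1`) stores exactly the type's
fields. Only the two-radial/two-tangential model is accepted at read
time; higher-order coefficients are rejected rather than silently
dropped. Calibration estimation itself is out of scope: parameters are
read from files (any planar-checkerboard tool can produce them), and
`reprojection_error` provides the validation half — RMS Euclidean
pixel distance between projected 3D points and observed pixels.
Distortion is inverted by fixed-point iteration, accurate to below
1e-8 in normalized coordinates for `|k1|, |k2| ≤ 0.3`.

The rotating-lifter acquisition (fixed camera, plant rotates) is
represented by the equivalent camera-ring formulation: `n` cameras
equally spaced in azimuth aimed at one target point. If external
calibrations encode the other convention they must be converted before
use; the package does not guess.

## Segmentation

The chain is register → frame difference → green superimposition → HSV
threshold → morphological cleanup. Registration estimates a similarity
transform (scale, rotation, translation — zoom drift is the dominant
nuisance) from ORB keypoint matches with RANSAC; below a floor of 10
inliers it falls back to the identity with a warning, so featureless
frames degrade gracefully. Frame differencing marks pixels whose
max-channel absolute difference exceeds `diff_threshold`
(default 15/255). The green test and the HSV threshold share one
inclusive band (defaults H 0.051–0.503, S 0.102–0.804, V 0.000–0.786);
the band is setup-dependent and fully overridable. Hue lives on a
[0, 1) circular scale; the default band does not straddle 0, so no
wraparound handling is applied. Cleanup erodes and dilates with disk
elements (defaults radius 1 and 1) and keeps the largest 8-connected
component if it reaches `min_area` (default 200 px). Equal erosion and
dilation radii were chosen deliberately: an asymmetric pair (e.g. 1, 2)
systematically shifts the silhouette boundary outward by one pixel,
which on a thin-leaved plant costs several percent of overlap accuracy
while a 1-px dilation already refills small interior holes.

## Space carving

The reconstruction volume is an axis-aligned grid of cubic voxels;
voxel `(i, j, k)` has centre `origin + edge·(i+0.5, j+0.5, k+0.5)`. A
voxel survives a view iff its centre projects (nearest-pixel lookup)
onto a foreground silhouette pixel; projections outside the image or
behind the camera count as outside (the latter are tallied in a
warning). The result over all views is a per-view set intersection:
order-independent, idempotent, monotone in the number of views, and a
guaranteed superset of the true object (the visual hull). A
"conservative" footprint mode projects the 8 voxel corners and keeps
the voxel if any corner lands inside. Only silhouette consistency is
used; no colour test. Default desk-scale resolution is 256³;
1200³-scale grids work but are not exercised by the tests. A
largest-26-connected-component filter guards the separation stage
against floating carving debris.

## Organ separation

Tracing starts at the lowest occupied layer and walks upward one
z-slice at a time; slice components are 8-connected in-plane.

* One component → accepted as stem.
* Several components → the *voxel overlapping consistency check*
  picks the component sharing the most (i, j) columns with the previous
  accepted slice (ties: smaller area, then nearest centroid; zero
  overlap falls back to nearest centroid with a warning).
* The accepted slice is then *trimmed* to a conical frustum between
  the previous stem disc and the current one (discs: centroid +
  equivalent radius `sqrt(area/π)`, 0.5 voxel slack). Three
  robustness refinements matter in practice, all motivated by junction
  slices where a leaf base merges with the stem in-plane: the disc is
  refitted iteratively to a fixed point (the raw slice's centroid and
  radius are biased by the attached leaf); the far radius may exceed
  the near one by at most 0.5 voxel per layer and the centre may drift
  at most 0.25 voxel per layer (a stem's cross-section changes slowly
  between adjacent layers — without these caps the frustum slides onto
  the leaf and the trace follows it); and the near radius anchors on
  the running median of accepted stem areas rather than the previous
  slice alone, so one contaminated layer cannot compound. Trimmed
  voxels are not deleted — they fall back into the leaf pool.
* Components smaller than `noise_area_fraction` (0.25) of the running
  median stem area are treated as reconstruction specks: they neither
  count toward the component count nor stand as stem candidates. The
  floor is relative, so a genuine 1-voxel-wide stem still traces.
* Tracing stops — fixing the TLC base `z_t` — when a slice stops
  looking like a stem: the (speck-filtered) component count reaches
  `max_components` (default 4), or the stem-candidate component's area
  exceeds `area_factor` (default 4.0) times the running median of the
  last `median_window` (10) accepted stem areas. Both rules must hold
  for `onset_persistence` (5) consecutive slices, with `z_t` backdated
  to the first offending slice; an empty slice stops immediately.
  The persistence gate exists because junction blobs and visual-hull
  phantoms offend transiently (their run length is bounded by a leaf's
  rise above its node), while the top-leaf cluster stays offending for
  its full height. The area test applies to the stem-candidate
  component rather than the whole slice because an arching leaf's flat
  apex run can dwarf the stem's cross-section far below the TLC.
  Consequence of the persistence default: a TLC shorter than about 5
  voxel layers would be missed (the trace would pass through it).

Everything at or above `z_t` is TLC. The remaining pool is clustered
by single linkage on voxel centres: two voxels share a leaf iff linked
by a chain of steps each ≤ `min_distance`. The threshold is expressed
in voxel-edge units with default 2.0: it merges all 26-adjacent voxels
(max step √3) and splits clusters separated by more than two voxels.
A sub-voxel threshold would be degenerate on a lattice — no two
distinct voxel centres are closer than one edge — so thresholds are
only meaningful at ≥ √3 edges. Clusters below `min_leaf_voxels` (20)
are reported as debris, not dropped. A pool cluster lying *entirely*
within `min_distance` of the stem or the TLC is absorbed into that
component: it is a trimming sliver or the TLC's bottom ring shed
during the onset lag, not an organ (a real leaf touches the stem only
at its node and extends far beyond the threshold). Because of this
absorption the TLC may contain a few voxels just below `z_t`. The
partition `|S| + |T| + Σ|leaf| + |debris| = |P|` is asserted on every
run. Leaves are numbered by the height of their lowest voxel (lowest =
first emerged); the ordering rule is an assumption, not a measured
emergence time.

The procedure assumes one distinct, roughly vertical, unbranched stem
with one leaf per node (maize-like architecture); bushy or branched
canopies are out of scope.

## Leaf skeletonization and length

Each leaf cloud is contracted onto its medial curve by Laplacian
contraction: an 8-nearest-neighbour graph with inverse-distance
weights defines a row-normalized graph Laplacian `L`; each iteration
solves the sparse normal equations of

    minimize ‖w_L · L X‖² + Σ_i w_{H,i}² ‖x_i − x_i^prev‖²

with the contraction weight `w_L` doubling per iteration and per-point
attraction weights growing with local shrinkage. Iteration stops when
the cloud's thickness — mean distance of each point to the best-fit
line of its 16-NN neighbourhood — falls below `thin_tol` (0.5) or
after `max_iter` (10). Points are pre-normalized by their median
nearest-neighbour spacing, which makes the procedure (and `thin_tol`,
effectively in voxel edges) scale-equivariant. The thickness metric
deliberately uses a larger neighbourhood than the contraction graph:
with few neighbours the local line overfits a noisy tube and
under-reports its width. A singular or diverging solve falls back to a
single PCA-line projection with a warning.

The contracted points are projected onto their two principal axes
(deterministic sign convention: largest-magnitude loading positive),
and `y = p(x)` is fitted by least squares with default order 4
(config-overridable; the residual is non-increasing in order, and the
order is reduced with a warning when it reaches the number of distinct
x values). Real leaves are 3D curves; the fit captures the dominant
in-plane bend and the out-of-plane RMS is reported as a quality
metric. Leaf length is `∫ sqrt(1 + p'(x)²) dx` over the skeleton's x
range by adaptive quadrature (relative tolerance 1e-8), converted to
mm by the voxel edge.

## Holistic phenotypes

All geometric volumes are computed on voxel centres without half-voxel
inflation, so ratios are bit-reproducible; counts are voxel counts and
physical volumes are `count · edge³`. The minimum enclosing sphere is
exact (Welzl's randomized incremental algorithm with a seeded shuffle,
run on convex-hull vertices for clouds above 300 points; the base case
returns the sphere with the support set on its boundary, which is what
makes the recursion exact). The minimum bounding cuboid fixes its
vertical axis (plants are gravity-aligned) and takes the exact
minimum-area oriented rectangle of the xy projection times the z
extent. Width vs depth of the axis-aligned cuboid is assigned by
magnitude (longer horizontal extent = width), not axis identity.
Degenerate inputs (coplanar clouds, zero extents) yield NaN "missing"
values rather than errors. Trajectories are per-day series of every
scalar phenotype with first differences as growth rates; no smoothing.

## Synthetic plants: what they emulate and what they do not

The generator builds a tapered vertical stem (linear radius taper), one
planar parabolic ribbon leaf per node with alternate 0°/180°
phyllotaxy plus azimuth jitter, and a dense ellipsoidal TLC capping the
stem. Leaf midlines are `z(d) = node + a·d − (a/D)d²` with takeoff
slope `a` (default 0.6) — the horizontal run `D` is chosen from the
requested arc length via the closed form `L = D·G(a)/a`,
`G(a) = (a√(1+a²) + asinh a)/2`, so truth lengths are analytic, and
leaves are planar by construction so the planar curve fit is exact on
the truth geometry. Default scale: 192×192×256 voxels, stem height
190, five leaves with arc lengths 85…50 (first-emerged longest), TLC
semi-axes 14×14×12. Leaf placement enforces a minimum clearance of 4
voxel edges between distinct leaves and between leaves and the TLC —
twice the clustering threshold, so cluster recovery is guaranteed by
construction; violations trigger re-jittered regeneration (up to 10
attempts). Stem voxels inside the TLC's height band carry the TLC
label, matching the operational definition that the stem ends where
the TLC begins.

Silhouettes are rendered by projecting voxel centres, rounding to the
nearest pixel and dilating by 1 px; this is exactly consistent with the
carver's lookup, so rendering-then-carving provably retains every model
voxel. RGB scenes paint the plant in one HSV colour on a homogeneous
gray background with optional Gaussian noise and a brightness offset on
the plant frame only; the scene mask is dilated by
`ceil(0.55 · pixels-per-voxel)` so the plant region is solid, like a
photographed plant rather than a point cloud.

What passing the synthetic suite does **not** show about real data:
leaves are untextured, untwisted single-colour ribbons with generous
clearances; there is no soil, pot, specular highlight, shadow or
colour gradient; silhouettes are exact (no motion blur or compression
artifacts); and the plant stands perfectly vertical. Segmentation
thresholds, the TLC-onset parameters and the clustering distance will
all need per-setup adjustment on real imagery — they are config
parameters for exactly that reason.

## Determinism and numerical choices

The only random number generator in the package lives in the synthetic
module and is seeded through the plant spec; everything downstream
(including Welzl's shuffle, which uses a fixed internal seed) is
deterministic, and two identical pipeline runs produce byte-identical
CSV/JSON/PLY outputs. Tie-breaks are explicit everywhere: slice
components order by area then lexicographic minimum index; leaf
clusters by lowest voxel, then mean height, then lexicographic minimum;
PCA axes carry a sign convention. Quadrature tolerance is 1e-8
relative; rotation orthonormality is validated to 1e-8; sphere-oracle
agreement holds to 1e-9.

## Problem sizes used by the test and acceptance runs

Unit tests run a 96×96×128-voxel 3-leaf plant; carving-oracle checks
use grids up to 32³ with up to 4 views against a scalar per-voxel
reimplementation; the randomized recovery suite uses twenty
192×192×256 plants; the end-to-end reconstruction demonstrations use
the default five-leaf plant at 192×192×256 with a 10-view,
1280×1280-pixel ring. These sizes were chosen so the entire suite runs
in a few minutes on one CPU while still exercising the full default
geometry.

## Known limitations

* Stems must be near-vertical and unbranched; the centre-drift and
  radius-growth caps assume lean well below one voxel per layer.
* A TLC shorter than `onset_persistence` layers is traced through, not
  detected.
* Leaf length on carved hulls is biased slightly long (hull fattening
  extends the leaf base and tip); on 8–10 view reconstructions of the
  default plants the median bias is a few percent.
* Colour/photo-consistency carving, mesh extraction, leaf width/angle
  phenotypes and separation of leaves inside the TLC are not
  implemented.
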