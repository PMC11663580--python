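# Methods

## Color model

Images are 8-bit sRGB. Conversion to CIELAB uses the standard chain
(gamma expansion → linear RGB → XYZ → L\*a\*b\*) with the D65 white point
and 2° observer — the sRGB standard — via scikit-image. All color
distances are plain Euclidean ΔE in (L, a, b); no ΔE94/ΔE2000 weighting is
applied, since the hull itself, not the metric, carries the shape of the
target volume.

Pixel colors are down-sampled into cubic voxels of side `bin_size`
(default 1.0 ΔE, roughly a just-noticeable difference) by floor division
of each axis. A voxel's representative color is its geometric bin center,
not the mean of its members: the center is independent of which pixels
happen to fall in the bin, so hulls built from voxels are reproducible
across images with the same occupied bins. The `min_pixels` filter
(default 20) drops voxels supported by fewer pixels, suppressing sensor
noise and rare boundary-transition colors before hull construction.

Background masking is represented as a per-pixel validity mask consumed by
voxelization and segmentation; it can be produced from a fixed Lab cuboid
in the run configuration or from a supplied mask file. Invalid pixels
contribute nothing downstream.

## Hull geometry

A target volume is `HullSpec(vertices, alpha, delta)`.

- `alpha = 0`: convex hull of the vertices (scipy Qhull), facets oriented
  outward.
- `alpha > 0`: alpha hull. The vertices are Delaunay-tetrahedralized and
  every tetrahedron with **any of its six edges** longer than `alpha` is
  discarded; boundary triangles (faces belonging to exactly one retained
  tetrahedron) form the surface, oriented away from their tetrahedron's
  opposite vertex. `alpha` is an absolute maximum edge length in ΔE units —
  not the circumradius convention of classical alpha shapes — because that
  is the natural reading of "limit edge length" and gives users a
  threshold in the same units as `delta`. Applying the limit to
  tetrahedron edges rather than only to boundary-facet edges was a
  genuinely open choice; tetrahedron edges were chosen because they make
  the retained solid itself (not just its skin) respect the scale limit,
  which is what makes disjoint clusters separate.

Degenerate vertex sets (< 4 points, collinear, coplanar) raise a
`DegenerateHullError` naming the deficiency rather than falling back to a
lower-dimensional hull: a 2D hull has zero volume and everything would be
classified by distance only, which silently changes the model. An `alpha`
so small that no tetrahedron survives raises `EmptyHullError`.

Containment uses the generalized winding number (summed signed solid
angles, Van Oosterom–Strackee form), thresholded at half a full turn. For
watertight outward-oriented meshes this is exact and extends to unions of
disjoint components without bookkeeping. Points with ambiguous winding are
resolved by surface distance ≤ 1e-9 (boundary counts as inside).
Distance-to-surface is the exact minimum over all facets of the
point-to-triangle distance, computed vectorized with barycentric
projection and edge clamping, chunked to bound memory at ~4M point-facet
pairs. The test suite checks both against independent oracles written
differently (ray-casting parity; Eberly's region-based scalar algorithm).

Classification is `inside(c) or dist(c, surface) ≤ delta`. The default
`delta = 5` ΔE is a visually conservative band; it absorbs 8-bit
quantization error (≤ ~0.5 ΔE) and the shell left uncovered when hulls are
built from voxel centers.

## Segmentation

`segment` classifies the unique pixel colors of an image once and
broadcasts verdicts to member pixels. Because the color → verdict map is
deterministic, this is *identical* to classifying every pixel
independently (asserted in tests); it is purely a speedup. Classifying
binned (voxelized) colors instead would be faster still but could not
guarantee per-pixel equality, so it is not done.

Post-processing: `remove_small` drops 8-connected foreground objects
below `remove_area`; `fill_holes` fills 4-connected, border-free
background components below `fill_area` (8/4 connectivity duality is the
standard choice). Removal runs before filling so debris cannot seal a hole
before it is measured. Both default to 0 (off). Dice of two empty masks is
defined as 1.0 (perfect agreement).

## Layout

Markers are detected on the luminance channel: Canny edges (σ = 2), a
circular Hough transform over [r_min, r_max], then greedy selection of the
`expected_n` highest-accumulator circles with center separation > r_min;
score ties break toward the top-left-most center. Centers are grouped by
single-linkage clustering cut at `cut_distance` — linkage and cut rule are
this package's choice; the cut should sit between the within-group unit
spacing and the smallest between-group distance. Groups are ordered by
centroid (top-to-bottom, then left-to-right); within a group, centers are
banded into rows with tolerance 0.5× the median nearest-neighbor spacing
(so a few pixels of jitter cannot permute indices) and sorted row-major
(or column-major), indices running 1..N across groups. Regions of interest
are discs of radius `radius + dilation`; contested pixels in overlapping
discs go to the nearest center. Fixed layouts can be supplied in the
configuration to bypass detection.

## Growth

Areas are foreground pixel counts per labeled region, optionally
calibrated by `scale`² (length per pixel). Time is in days, parsed from
filename timestamps with a configurable named-group regex plus strptime
format; images sort by parsed time with lexicographic tie-break. RGR is
the OLS slope of ln(area) on time. Zero-area records are excluded from the
fit and flagged `ZeroArea` rather than pseudo-counted — a pseudo-count
would bias the slope by an amount depending on an arbitrary constant.
Fewer than two positive-area points (or no time spread) yields no fit and
`TooFewPoints`.

`ModelFitOutlier` is advisory and set when the ln-area residual standard
deviation exceeds 0.3 **or** r² falls below 0.7 (both configurable, either
disabled with `None`). The thresholds are this package's defaults: 0.3 on
the log scale corresponds to ~±35% area excursions around the trend, well
beyond segmentation noise on a clean series. Group summaries average RGR
over unflagged fits only, but every unit always appears in the per-unit
table.

## Synthetic fixtures

The generator emulates the structure of a phenotyping array: a light gray
background (Lab ≈ (70, 0, 0) ± 2), dark fiducial rings on a grid with
optional integer jitter, and one target blob per unit — a disc with
sinusoidal boundary perturbation (amplitude 0.12, 5 lobes) whose area
follows A₀·e^(r·t) with multiplicative log-normal noise. Blob colors are
sampled uniformly from a cuboid shrunk by 50% inside an 8-vertex truth
hull in the green region of Lab space; background and marker colors sit
tens of ΔE from the hull surface, far beyond 3·delta, so a well-formed
fixture is exactly separable by construction. Truth areas are the
generator's own pixel counts of its rasterized blobs (never the analytic
disc area), and truth layout/indexing follow from construction order, so
every downstream quantity has an independent ground truth. Default
conditions: 2 groups × 2×3 units, 6 timepoints at 1 day, A₀ = 120 px,
r = 0.25 day⁻¹ — sizes chosen so a series generates in well under a
second while every unit's blob clears rasterization granularity.

What the fixtures do **not** emulate: illumination gradients, shadows,
specular highlights, chromatic aberration, occlusion by apparatus (mesh,
ring glare), and gradual color drift of senescing tissue. Passing the
fixture-based tests therefore demonstrates correctness of the *machinery*
(geometry, classification, counting, fitting) under the stated color
model, not robustness to real-image nuisance variation — on real data the
hull and `delta` must actually cover the tissue's color distribution,
which is exactly the calibration the tool's hull-from-mask and prior
mechanisms support.

## Numerical choices and limitations

- Boundary tolerance 1e-9 ΔE for "on the surface"; winding threshold 0.5
  turns; facet-degeneracy guard 1e-300 in denominators.
- Coplanar convex-hull faces may triangulate differently across Qhull
  versions; equality is always asserted via enclosed volume and
  point-classification agreement, never facet lists.
- `residual_std` uses n − 2 degrees of freedom (n − 1 when only 2 points).
- Config files are TOML; floats are emitted with `repr`, which
  round-trips IEEE doubles exactly through decimal text.
- Alpha-hull surfaces from tetrahedron filtering can in principle touch at
  a single vertex or edge (non-manifold contact); winding-number
  containment remains correct there, but `is_watertight` reports the
  strict edge-pairing property only.
- Hulls built from voxel centers shrink coverage by up to half a bin
  diagonal; the `delta` band compensates. With `delta = 0` and
  mask-derived hulls, expect a thin rim of missed pixels.
- Hough detection assumes marker radii within the configured band and
  roughly circular, unoccluded rings; heavily occluded markers need the
  fixed-layout escape hatch.
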