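# Methods

## Problem setting

Corneal endothelial mosaics imaged by specular microscopy are tessellations
of bright, near-hexagonal cells separated by thin dark borders, degraded in
practice by illumination gradients, blur, noise, and — in Fuchs dystrophy —
dark guttae that interrupt the mosaic. Annotated segmentation masks are
scarce. The package augments an annotated set geometrically: each image and
its mask are deformed together by a piecewise affine warp anchored on the
mask's own structure, so augmented annotations remain pixel-exact.

## The warp model

**Keypoints.** The keypoint set K is the union of (a) one interior point per
mask region — the region's area centroid, rounded to the pixel grid with
round-half-to-even — and (b) a fixed border lattice: points at fractions
{0, 1/8, …, 7/8, 1} of each edge, at pixel positions round(f·(size−1)),
corners shared, 32 unique points. Minimum image side is 9 px; below that the
rounded fractions collide. Coordinates are 0-based (x = column, y = row),
pixel-centre convention.

**Shift law.** Interior keypoints are displaced per axis by δ = R·d_min/s,
R ~ U(−1, 1) independently per keypoint and axis; border keypoints are
frozen. The distance floor d_min is the minimum over keypoint pairs of the
per-axis-min metric d(a, b) = min(|xa−xb|, |ya−yb|). Two policies make this
well defined in practice:

- the minimum is taken over interior–interior pairs only (the collinear
  border lattice forces the metric to zero);
- the result is floored at 1 px at sampling time. With centroids on the
  integer grid, two of them share a row or column at any realistic cell
  density, so the floor is the operative scale and shifts are sub-pixel.
  This is faithful to the per-axis-min definition; the Euclidean or
  Chebyshev alternatives would give larger, scale-dependent shifts and are
  deliberately not substituted.

The strain parameter s > 0 inversely controls deformation (bound d_min/s per
axis). The useful regime is s ∈ [1, 3]; batch defaults draw
s ~ U(2, 3), spanning strong (s = 2) to mild (s = 3) deformation.

**Triangle correspondence.** A Delaunay triangulation is computed on the
*shifted* set K′ and its index triples are imposed on K, giving a single
shared connectivity — the only way the per-triangle affine family is well
defined, since independent triangulations of K and K′ need not match.
(`connectivity_side="source"` triangulates K instead.) Each triangle pair
determines one affine map solved exactly from its three vertex
correspondences; vertex images are reproduced to ≤ 1e−9 px.

**Validity and rejection.** A sampled warp is accepted only if every
triangle has strictly positive signed area on *both* sides (no fold-over),
which certifies the piecewise map is a bijection of the image rectangle, and
if the warped mask keeps every region id as a single 4-connected component
(regions supplied fragmented are not required to heal). Rejection triggers a
fresh draw under a new sub-stream, up to `retry_budget` (default 20). This
automates the manual plausibility screening that bounded-warp augmentation
otherwise needs.

**Resampling.** Output pixels are pulled through the inverse map: bilinear
interpolation for intensities, nearest-neighbour for labels (never blended).
Inverse-mapped coordinates within 1e−5 px of the pixel grid are snapped onto
it, making identity maps (and the s → ∞ limit) reproduce the input
bit-exactly. The default warps the label raster and re-derives the boundary;
warping the thin binary boundary raster directly is supported
(`mask_warp="boundary"`), at the cost of renumbered region ids.

## Watershed refinement

Nearest-neighbour label resampling leaves ragged borders. The warped mask is
repaired by marker-based watershed over the warped image:

- **Markers**: each region eroded by `marker_erosion_radius` (default 2 px),
  implemented with one distance transform to the two-sided boundary set;
  regions erased by erosion are restored as a single-pixel marker at their
  most interior point.
- **Elevation**: Sobel gradient magnitude (default) or inverted intensity,
  Gaussian-smoothed with `elevation_smoothing` (default 1 px). Smoothing
  matters: a dark border band produces twin gradient ridges with a contested
  valley between them where flood order, not elevation, would place the
  line; one merged central ridge makes line placement stable.
- **Flooding**: 4-connected. This keeps every basin a 4-connected region and
  the implied interfaces 8-connected one-pixel curves (the standard digital
  4/8 duality); 8-connected flooding measurably leaves diagonal debris along
  the lines.
- **Fixed point**: the marker/flood/merge step is iterated until the mask
  stops changing (≤ `max_iterations`, default 5; convergence is typically
  reached in 2–3 passes), making refinement exactly idempotent for a fixed
  elevation rather than approximately so.
- Regions below `min_region_area` (default 5 px) are merged into their
  largest neighbour, absorbing isolated-point artefacts; merges are logged.

Marker-based seeding guarantees region-count preservation. On clean
synthetic mosaics warped near-identity, refined masks match generator ground
truth exactly outside a 1-px boundary band, and every refined boundary pixel
lies within 2 px of a true boundary. The converse bound is not attainable by
any refiner: where two borders merge into a wide uniform dark wedge, the
true line's position inside the plateau leaves no image evidence.

## Synthetic mosaics

The generator emulates endothelial images with exact ground truth: cells are
the Voronoi partition of n seed pixels (endothelial tessellations are
near-Voronoi), drawn by dart throwing with exclusion radius 0.45·√(hw/n)
(relaxed geometrically if unfillable) because real cells are near-uniform in
size and unconstrained seeding produces degenerate slivers. The partition is
repaired so every region is one 4-connected component. A chosen fraction of
cells is flagged as guttae and rendered dark; the render applies per-cell
intensity variation (interiors U(0.60, 0.85), guttae U(0.05, 0.15), borders
0.15), a smooth multiplicative illumination ramp of relative amplitude
`illumination_amplitude`, additive Gaussian noise (`noise_sd`, [0, 1]
units), then Gaussian blur (`blur_sigma`), clipped and quantized to the
16-bit grid so disk round trips are exact. All randomness flows through
counter-based Philox streams keyed by the spec seed; identical specs give
bit-identical rasters.

What the generator does *not* model: specular glare, defocus fields that
vary across the image, instrument-specific fixed-pattern noise, guttae that
straddle several cells, and the intensity statistics of real endothelium.
Tests passing on these mosaics therefore validate the geometric and
topological guarantees of the pipeline (bounds, bijectivity, region
preservation, refinement convergence), not segmentation accuracy on
clinical images.

## Batch workflow and reproducibility

`augment_dataset` draws `n_outputs_per_input` strain values per input from
`s_range`, runs warp + refine, and writes image, mask, and a sidecar JSON
(source names, s, derived seed, d_min, retries, per-keypoint shifts). Every
random stream is a Philox generator keyed by SeedSequence(seed, path), where
the path encodes pair index, output index, and retry attempt — so batch
reruns are bit-identical and any single output is replayable from its
sidecar alone (`replay_sidecar`). The run report records successes,
rejections, retries, and the achieved dataset multiplier; unreadable inputs
are skipped with a logged error, and only a run with zero outputs fails.

## Metrics

Confusion counts are exact pixel tallies. Dice = 2TP/(2TP+FP+FN),
accuracy = (TP+TN)/total, IoU per class with mIoU the unweighted two-class
mean; 0/0 is defined as 1 (empty-vs-empty agreement). Because "mIoU"
sometimes means foreground-only IoU, both per-class IoUs are reported
alongside the mean.

## Numerical choices and edge cases

- Triangle orientation is normalized counter-clockwise in the (x, y)
  algebra; validity checks use strict positivity of signed areas.
- Point location uses the Qhull locator on the triangulated side and a
  vectorized barycentric search on the imposed side; points on shared edges
  may resolve to either adjacent triangle, which is harmless because the
  affines agree on the edge.
- Cocircular point sets admit several Delaunay triangulations; any is
  accepted, and no downstream property depends on the choice.
- Duplicate centroids after rounding are merged (logged); a centroid that
  lands exactly on a border lattice point is dropped in favour of the fixed
  border point (logged).
- Boundary-mask inputs are converted to labels by 4-connected labelling of
  non-boundary pixels; frame-touching components larger than half the image
  are treated as background, and sub-5-px pinch-off debris at triple
  junctions is folded back into the boundary so round trips preserve region
  counts.
- Multi-channel TIFs are reduced to channel 0 with a logged warning.

## Problem sizes

Tests and the acceptance script run on 96×96 mosaics with 15–40 cells —
matching the patch geometry the method targets — with 50–1000 Monte-Carlo
repetitions per property; the whole suite completes in seconds on one CPU.

## Known limitations

- Under the per-axis-min distance with integer centroids, d_min is almost
  always at the 1 px floor, so single warps are sub-pixel; visible
  deformation accumulates through the s-range sampling and multiplicity of
  the batch workflow rather than through any one draw.
- Watershed refinement assumes borders darker or sharper than cell
  interiors; inverted-contrast imagery should use
  `elevation_mode="inverted_intensity"`.
- The border lattice is only mirror-symmetric when (size−1) is divisible
  by 8; for other sizes the rounded half-fraction point breaks exact flip
  symmetry by one pixel.
- Region ids must fit uint16 for mask files on disk.
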