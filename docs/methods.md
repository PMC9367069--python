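# Methods

This note documents the models, conventions, and numerical choices behind
`tissuegraph`, and what the synthetic generators do and do not emulate.

## Coordinate and unit conventions

Arrays are indexed in image order, `(y, x)` in 2D and `(z, y, x)` in 3D, and
`spacing` gives the physical pixel size per axis in that same order.  All
exported quantities are physical: coordinates are pixel indices scaled by
spacing and reported as `x, y(, z)` (x = column axis), areas/volumes are
pixel counts times the pixel measure, and angles are measured in the
physical frame.  A pixel's position is its index, not its center offset by
half a pixel: the constant offset cancels in every distance and moment, and
the convention keeps round-trips exact.  Label values may be any positive
integers — segmentation tools renumber freely, so no contiguity is assumed.

## Per-cell measurement

Centroid and size are first moments: the mean of member-pixel coordinates
and the count times the pixel measure.  Shape comes from the second central
moment (covariance) matrix of the member-pixel coordinates computed in
physical units, so anisotropic voxels (z-spacing ≠ xy-spacing, the rule in
light-sheet and confocal stacks) yield physically correct orientations.
With eigenvalues λ₁ ≥ … ≥ λ_d:

* eccentricity = √(1 − λ_d/λ₁).  In 2D this is the standard ellipse
  eccentricity; the same single formula is used in 3D (ratio of the
  smallest to largest principal variance) rather than one of the several
  inequivalent 3D "eccentricities" in the literature, because it needs no
  rank-specific casing and degrades gracefully for near-isotropic masks.
* θ is the major-axis (λ₁ eigenvector) angle.  2D: angle with the x-axis
  folded into (−π/2, π/2] — an axis has no sign.  3D: θ is the polar angle
  and ψ the azimuth of the major axis, the sign fixed so the z (then y,
  then x) component is non-negative.
* Degenerate masks (single pixel, or λ₁ = 0) return eccentricity 0 and
  angles 0 by convention.

Mean fluorescence is the arithmetic mean of a channel over the mask pixels;
no saturation exclusion or background subtraction is applied.  Threshold
phenotyping is strict (`mean > threshold` ⇒ positive): ties are
measure-zero on real intensities but the rule must be deterministic, and
"above" reads most naturally as strict.

## Graph construction

The **geometric** rule uses a closed ball, `0 < d ≤ dmax`, found with a k-d
tree and verified edge-by-edge.  The **Delaunay** rule takes the 1-skeleton
of `scipy.spatial.Delaunay` and deletes edges with `d > dmax`.  Making both
cutoffs inclusive makes them identical at the boundary, which in turn makes
"Delaunay-with-cutoff ⊆ geometric at the same dmax" an exact invariant the
tests rely on.  Degenerate point sets (collinear/coplanar, or fewer than
ndim + 1 points) cannot be triangulated; the builder falls back to the
geometric rule with a warning and records the fallback in the graph
metadata, because aborting a batch run over one degenerate field of view is
worse than a well-labeled approximation.  Exact cocircular ties are left to
the triangulator's tie-break; any valid triangulation is accepted.
Coincident centroids (a real segmentation artifact) produce a warning and a
suppressed zero-length edge, never a self-loop.

The **contact** rule counts face-adjacent pixel pairs with different
positive labels — 4-connectivity in 2D, 6-connectivity in 3D.  Corner
adjacency is deliberately excluded: a corner contact has zero physical
measure, and counting it would quantize `contact_size` upward.  Faces are
accumulated per orientation with their physical measure (a face
perpendicular to axis k has measure ∏spacing/spacing[k]), so anisotropic
voxels yield correct contact areas.  `touch_distance` (default 1 = strict
abutment) handles membrane-stained segmentations that leave a thin
background ridge between cells: labels are grown into the background by
`touch_distance − 1` pixels before counting.  The growth is competitive
nearest-label expansion (`skimage.segmentation.expand_labels`) rather than
independent per-mask dilation: independent dilations can overlap, leaving
"which cell owns this pixel" — and hence the face count — ill-defined,
while competitive expansion keeps labels disjoint and bridges ridges
identically.

## Analyses

Degree and link-length statistics are population moments (SD with n, not
n−1) over nodes and edges respectively; an empty graph reports its mean as
absent rather than NaN-poisoning downstream tables.

**Layer peeling.**  Two definitions are implemented because the two input
regimes need different information:

* *hull-peeling* (default): layer 0 is the set of centroids on the convex
  hull; remove them, recompute, iterate.  When fewer than ndim + 1 points
  remain, or the remainder is degenerate (collinear/coplanar), they all
  receive the next index and peeling stops — the hull is undefined there
  and a deterministic terminal rule beats an error.  Works for point clouds
  and nuclei-only segmentations.
* *background-contact*: layer 0 is every cell whose mask face-touches
  background or the image border; deeper cells are indexed by minimum hop
  count to layer 0 in the contact graph, so a layer-k cell always has a
  layer-(k−1) neighbor.  Cells unreachable from the surface (rare,
  disconnected islands) get the next index after the deepest reachable
  layer.  In a gap-free tiling the only background contact is the image
  border, which is then the correct surface definition.

The per-layer link-length profile defaults to *incident* averaging (all
edges touching the layer) rather than intra-layer-only, because inner layers
of a spheroid can hold few cells and no intra-layer edge at all; the strict
intra-layer variant is available via a mode flag.  Cluster statistics are
reported both for all clusters and restricted to size ≥ 2, since "fraction
of cells in a same-type cluster of two or more" is the usual headline
number.

## Synthetic tissues

`generate_voronoi_tissue` rasterizes the Voronoi tessellation of n random
generators (rejection-sampled to a minimum separation): each pixel takes the
label of its nearest generator, ties to the lowest index for grid
determinism.  By Voronoi–Delaunay duality the ground-truth adjacency is the
generator Delaunay edge set, which is what makes the contact builder
testable end to end.  `membrane_gap > 0` blanks pixels whose two smallest
generator distances differ by less than the gap — an ~gap/2-wide background
ridge along every boundary, emulating unstained membranes.  Defaults (30
cells on 512², separation 20 px, gap 0) give cells of realistic pixel
footprint (~90 px across) while keeping the duality check exact.

Intensities follow a per-type Gaussian model: one draw per cell
(mean/SD per type and channel) plus i.i.d. per-pixel noise (SD 50), clipped
at zero.  The default model places two populations at 4000 and 9000 with SD
500 — five SDs on either side of a 6500-style threshold, so threshold
phenotyping should make zero errors and any misclassification is a bug, not
noise.

`generate_spheroid_cloud` samples centroids uniformly in a 3D ball with
sequential minimum-separation thinning and i.i.d. categorical types.
Defaults — 300 cells, radius 75 μm, separation 12 μm — approximate a
mesenchymal-stromal-cell-sized aggregate imaged volumetrically: nuclear
neighbor spacing in the low tens of micrometres and a graph of ~10–16
neighbors per cell under a Delaunay rule with a 40 μm cutoff (the cutoff
prunes hull-spanning simplex edges while keeping all physical neighbors).

What the generators do **not** emulate: real mask shapes (Voronoi cells are
convex polygons; real cells are not), intensity textures, point-spread
blur, segmentation errors (merges/splits), radial density gradients in
spheroids, and anisotropy of real 3D acquisitions.  Tests passing on these
fixtures therefore demonstrate the *graph machinery* is correct given a
faithful segmentation — they say nothing about segmentation quality, which
is upstream and out of scope.

All randomness uses numpy's PCG64 `default_rng`, named in fixture metadata;
identical spec + seed reproduces outputs byte-for-byte.

## Numerical choices and tolerances

Float round-trips through CSV/GraphML are checked at 1e-9; distances are
recomputed from centroids rather than trusted from intermediates.  The
duality test between the rasterized contact graph and the continuous
Delaunay truth uses a guard band: spurious-edge checks filter contacts at
> 2 pixel faces, while completeness is asserted only for truth edges whose
continuous Voronoi ridge, clipped to the image, is at least 4 px — a ridge
shorter than a few pixels may legitimately rasterize to nothing, and a
knife-edge equality would test pixelation, not the builder.  Problem sizes
in the test suite (50-point oracles, 2,000-point Delaunay limit, 500-point
peeling, 512² duality images over 10 seeds) were chosen so the full suite
runs in well under a minute while keeping every statistical band (e.g.
interior mean degree in [5.8, 6.2]) comfortably non-flaky at fixed seeds.

## Known limitations

* The contact rule assumes masks tile the tissue up to thin ridges;
  `touch_distance` is a pragmatic bridge, not a membrane model.
* Hull peeling is a geometric surface definition; for very aspherical
  aggregates the convex hull overestimates the surface layer.
* No periodic boundaries, Gabriel/kNN/alpha-complex rules, or
  spatial-statistics tests (Moran's I, neighborhood enrichment) — the graph
  is exported precisely so such analyses can run downstream.
* GraphML serialization stores scalars only; vector attributes must be
  flattened (per-channel means are stored as `mean_<channel>` keys).
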