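# Methods

## Coordinate conventions

Streamline points live in the TrackVis "voxmm" convention: voxel-size-scaled
coordinates with a **corner** origin, so voxel (i, j, k) of the streamline
header's grid spans the half-open box [i·vsₓ, (i+1)·vsₓ) × … in the axis
order the header declares (`voxel_order`). Voxel lookup is
floor(coordinate / voxel_size) per axis after axis reordering; a point
exactly on a box boundary therefore belongs to the higher-index voxel of the
*streamline* grid — a deterministic tie-break that is asserted in tests.

`reconcile_affine` builds the 4×4 map from grid voxel indices to voxmm voxel
centers. The axis permutation and sign flips are derived purely from the two
orientation labels (grid `axis_codes` vs header `voxel_order`), never from
dimension heuristics, so equal-dimension cubic grids reconcile correctly.
Dims must agree after permutation and voxel sizes within 10⁻³ mm, else a
reconciliation error lists both descriptions.

TRK I/O is a small in-package codec for the fixed 1000-byte v2 header plus
float32 point payload. The deciding requirement was bit-faithful access to
the file's native voxmm coordinates (round-trip tests demand exact
equality); general-purpose readers expose only world-transformed points,
which reintroduces ~10⁻⁷ rounding per round trip. A test cross-checks the
codec against nibabel's TRK reader through the voxmm→RAS-mm affine. NIfTI
volumes go through nibabel.

## The path-length map

For each streamline: vertices are classified ROI-interior by voxel
membership; cumulative arc length is the running sum of Euclidean segment
lengths; each vertex's distance is the minimum |cumlen(k) − cumlen(m)| over
interior vertices m (nearest interior vertex in *either* direction — the
map is a shortest distance, not a first-entry distance); each vertex
deposits its distance into its voxel and the map keeps the per-voxel
minimum. Unvisited voxels hold the fill value, default −1 (configurable).

Deliberate choices, both configurable in effect and documented limitations:

* **Vertex-based visitation.** A segment crossing a voxel without a vertex
  in it deposits nothing. The mitigation is `densify`, linear interpolation
  until no segment exceeds a step bound; the pipeline default is half the
  smallest voxel size, which guarantees a vertex in every voxel a segment
  passes through more than trivially. Densification preserves total arc
  length to ~10⁻¹² relative (vertices are interpolated in float64).
* **ROI membership by voxel, not by Euclidean distance to the ROI surface**
  — the only definition consistent with the grid the map is written on.
* **No partial-segment interpolation into boundary voxels.** Distances are
  exact sums of vertex-to-vertex chords, which keeps the brute-force oracle
  bit-identical to the fast implementation (tested exactly on 50 randomized
  phantoms) at the cost of up to one vertex spacing of discretization.

`path_length_oracle` re-implements the contract as plain-Python exhaustive
enumeration with its own affine/floor arithmetic. It is the independent
check; the fast path uses vectorized binning and a sorted-search over
interior cumulative lengths.

## Streamline selection and tracking

*Targeting* keeps streamlines with ≥ 1 ROI-interior vertex (order
preserved, idempotent). *CCI* resamples each streamline to `subsample_n`
equally spaced vertices, computes the minimum average direct-flip distance
(MDF) per pair, and scores CCIᵢ = Σⱼ (1/MDF(i,j))^power over neighbours with
0 < MDF ≤ max_dist. Defaults: subsample 12, power 1, max_dist 5 mm — the
reference defaults for this statistic; duplicates (MDF = 0) are excluded
from the sum and logged. Filtering keeps scores strictly > 1 by default.
Whether CCI filtering belongs in the quantitative pipeline or only in
visualization is genuinely open; it is therefore an opt-in stage
(`cci_filter`, default off) rather than a silent default.

The deterministic tracker seeds one streamline per voxel center where
FA > 0.15 and propagates bidirectionally in `step_size` steps along the
local direction, sign-aligned with the incoming heading. A step is refused —
terminating the streamline — when the new position's FA ≤ threshold, the
turn exceeds 60°, the position leaves the grid, or the length cap
(default 250 mm) is reached. FA and directions are nearest-voxel lookups,
not trilinear: phantom expectations stay exact, at the cost of realism
relative to clinical Q-ball/HARDI trackers, which are out of scope.

## CTV construction

EPL thresholding is inclusive (fill excluded, 0 and EPL included), so masks
nest exactly over increasing EPL. Dilation is metric: a voxel joins the
dilated set iff its center lies within r world-mm of a source-voxel center,
via `scipy.ndimage.distance_transform_edt` with the voxel sizes as sampling
— exact for anisotropic voxels (clinical DW-MRI grids are commonly
1.09 × 1.09 × 2 mm), and verified exhaustively against a brute-force
distance scan on small grids. The 5 mm island-suppressing expansion applies
to the anisotropic union only, not the isotropic control; brain clipping
applies to both by default (`clip_isotropic_to_brain` can disable it for
the control, since treatment-planning practice varies). No separate
island-removal pass exists beyond the 5 mm expansion.

Slice contours use marching squares at level 0.5 per axial slice; loops pass
through voxel-edge midpoints, so voxel centers are never on an edge and
even-odd rasterization of the polygons reproduces the mask exactly at
voxel-center sampling (holes emerge as separate loops). Contours are
reported in world mm.

`compare_ctvs` reports world-mm³ volumes, the percent difference
100·(vol(a) − vol(b))/vol(b) — antisymmetric under swap only up to the
changed denominator — and recurrence coverage fractions (undefined/None for
an empty recurrence).

## Phantoms

Phantom generation is a pure function of its spec (seed included). Bundles
are straight lines or circular arcs sampled at a fixed arc-length spacing;
lateral jitter is a per-streamline constant offset in the tangent-orthogonal
plane, Gaussian truncated at 3 sd so containment is preserved and arc-length
expectations hold approximately. FA is 0.8 inside a 2-voxel corridor around
each centerline and 0 elsewhere; the direction field is the tangent of the
nearest centerline sample. The phantom world frame coincides with the voxmm
frame (corner origin, RAS), making frame reconciliation exact by
construction. `expected_wmpl` produces closed-form per-voxel expectations
for jitter-free bundles (tolerance: one vertex spacing plus the in-voxel
arc spread) and refuses jittered ones.

What phantom tests show: the geometry pipeline — coordinate reconciliation,
arc-length accounting, thresholding, metric dilation — is correct to its
stated tolerances. What they do not show: anything about tractography
fidelity on real diffusion data (no diffusion signal, no crossing fibres,
no noise model, no anatomy).

## Problem sizes and numerics

Randomized oracle-equivalence phantoms use 18×18×14 grids with 1–3
streamlines so the exhaustive oracle stays fast; the analytic quarter-circle
check uses r = 20 mm at 1 mm vertex spacing on a 0.5 mm grid, where the
chord-vs-arc deficit bound is L·Δθ²/24 ≈ 0.003 mm, well inside the 0.05 mm
assertion. The expansion-radius measurement uses a 48³ grid at 0.5 mm with
an 8³-voxel cubic GTV, where the tolerance is half a voxel diagonal
(≈ 0.43 mm). Exact-equality assertions (implementation vs oracle,
determinism, re-runs from a resolved config) are intentional: both sides
perform the same IEEE-754 double operations.

## Known limitations

* Streamline dialects other than TRK v2 (TCK, VTK) are not read.
* No image resampling/registration: all masks must share the WMPL grid.
* Vertex-based visitation plus no partial-segment interpolation biases WMPL
  up to one (densified) vertex spacing.
* The tracker is a contract-testing minimal implementation, not a
  reconstruction method.
* DICOM-RT export, dose calculation, and planning-system scripting are out
  of scope; slice contours are the vendor-neutral hand-off.
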