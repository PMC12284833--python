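# Methods

## The parcellation model

A bronchopulmonary segment is the lung territory ventilated by one tertiary
(segmental) bronchus. The package models a segment mask as the Voronoi-like
partition of each lobe by its labeled segmental bronchi: voxel `v` of lobe
`L` receives

    s(v) = argmin_{k in segments(L)} d_k(v),

with `d_k(v)` the Euclidean distance in mm from the voxel center to the
labeled centerline point set of segment `k`. The point set is the entire
tertiary branch plus all downstream sub-branches (not just the annotated
click point), densely resampled along edges at half the minimum voxel
spacing and rasterized to voxel centers. Restricting candidates to the
voxel's own lobe caps the search at five segments (the right lower lobe) and
makes lobe boundaries hard constraints. Ties are broken toward the smallest
segment code; background voxels of the lobe mask stay background.

Two implementations of this argmin exist deliberately:

- the production path computes one Euclidean feature transform per candidate
  segment (`scipy.ndimage.distance_transform_edt` with `return_indices`) and
  then *recomputes* each winning distance from the returned nearest-voxel
  index with a single shared squared-distance expression;
- the exhaustive path scans every (voxel, labeled voxel) pair with the same
  expression.

Because both routes evaluate identical floating-point expressions on integer
index deltas, they agree voxel-for-voxel — including at exact ties — whenever
voxel spacings are binary fractions (all phantoms use 1 mm). The phantom's
ground-truth mask is produced by the exhaustive path, so "production equals
ground truth" is a real cross-check. With irrational spacings, equality at
exact geometric ties can in principle fall to floating-point rounding; no
such case arises on the grids used here.

### Lobe regularization

`regularize_by_lobes` makes an arbitrary segment mask consistent with a lobe
mask: segment labels outside the lung are cleared; voxels whose segment does
not belong to their lobe (or is unlabeled) take the label of the nearest
voxel that already carries a valid in-lobe segment, via the same feature
transform. A lobe with no valid voxels at all falls back to its
lowest-numbered segment with a logged warning. The operation is idempotent.

### ROI cropping

`crop_resample` builds an axis-aligned box spanning the carina and
sternum-tips landmarks, expanded by configurable per-axis margins (defaults
150 / 100 / 150 mm per side — generous enough to cover both lungs from
mid-thorax landmarks), clips it to the volume, and resamples to isotropic
spacing (default 2 mm): trilinear for scalar volumes, nearest-neighbor for
labels. The identity configuration (box covering the whole volume, unchanged
spacing) reproduces the input voxel-for-voxel.

## Centerline probability maps

The tracer's input is a scalar map `p(v) = exp(-D(v)^2 / (2 sigma^2))` where
`D(v)` is the anisotropy-aware Euclidean distance transform of the rasterized
centerline. This form guarantees `p = 1` exactly on centerline voxels and a
strictly monotone decay with distance, which is what makes the map usable as
a marching speed. `sigma` (default 1.0 mm) sets the effective tube radius:
with the tracer's default foreground threshold of 0.05, the foreground tube
extends to `sigma * sqrt(2 ln 20) ≈ 2.45 sigma`. Rasterization samples every
edge at half the minimum spacing, which makes each edge's voxel chain
26-connected by construction.

## Tracing: geodesic times + iterative backtracking

Arrival times solve a first-arrival problem with speed
`F(v) = max(p(v), speed_floor)` from a seed voxel. They are computed as
minimum geodesic travel cost on the 26-connected lattice
(`skimage.graph.MCP_Geometric`, cost `1/F`, anisotropic sampling), which
matches the continuous eikonal solution exactly along lattice axes and
within small metrication error on oblique paths. The positive floor
(default 1e-4) keeps every voxel reachable, so a short stretch of zeroed
probability — a tracing gap — adds a large but finite time penalty instead
of disconnecting the far side; this is what lets one rooted tree span a
gapped bronchus.

The backtracking loop then repeats until a coverage target is met:

1. pick the uncovered foreground voxel with the largest arrival time and
   snap it to the local probability ridge (greedy 26-neighbor ascent, so
   emitted branch tips are centerline points rather than tube-shell voxels);
2. slide downhill on trilinearly interpolated `T` in steps of `step_mm`
   (default half the minimum spacing), with a discrete lowest-neighbor
   fallback where interpolation plateaus, until the path comes within
   `coverage_radius_mm` of an existing tree node or reaches the seed;
3. emit the path as a node chain parent-linked at the attachment point, or
   discard it if it is shorter than `min_branch_nodes` or exceeds a step
   budget of 10x the straight-line distance;
4. erase a ball around every path point from the uncovered set. The erase
   radius is `max(coverage_radius_mm, erase_radius_scale * r_local)` where
   `r_local` is a 3-voxel-neighborhood maximum of the foreground distance
   transform — a tube-radius estimate that stays valid when the path rides
   slightly off-axis — and the ball is measured from the exact path point so
   everything inside the attachment radius of a node is always erased.

Radius-proportional erasure keeps wide tubes from leaving uncovered shells
(which would spawn spurious branches), while the default scale of 1.0 keeps
the erasure tight enough not to swallow short daughter branches that diverge
at shallow angles. Discarded fragments still erase their source, so every
iteration strictly shrinks the uncovered set and the loop terminates; the
stop conditions are the coverage fraction (default 0.98) or exhaustion of
the foreground. Given a fixed map, parameters, and seed, the output tree is
bit-identical across runs.

Node radii are read off the foreground distance transform at each node.
The default seed is the global probability maximum (ties toward the lowest
linear index); pipelines that know the tracheal origin should pass it
explicitly, which roots the tree anatomically.

## Evaluation metrics

Per segment: Dice `2|A∩B|/(|A|+|B|)`; surface distances from 6-connected
surface voxels (volume-border voxels count as surface) pooled symmetrically,
with HD95 the 95th percentile (linear interpolation between order
statistics) and ASSD the mean; and the inclusion rate — the fraction of the
segment's labeled centerline points lying on voxels predicted as that same
segment. The inclusion denominator counts only points on predicted-lung
voxels, so gross lung under-segmentation shows up separately instead of
silently deflating the rate; the all-points variant is emitted alongside it
in the JSON report. Aggregates are mean and sample (n−1) SD over segments
where the metric is defined; segments missing from either mask are excluded
and flagged. Dice is reported on 0–1 and conventionally printed x100.

## Synthetic phantoms

`phantom.generate` builds, from a single seeded generator drawn in fixed
traversal order: two ellipsoidal lungs; a trachea descending to a carina;
left/right main bronchi; 3 + 2 lobar bronchi steered toward per-lobe
targets; exactly 18 segmental bronchi distributed 3/2/5/4/4 with
cone-distributed directions (mean branch angle 35 deg ± 8), azimuthally
spread siblings, and a minimum pairwise separation between first labeled
points of 1.2 voxel diagonals; and one further generation of two diverging
sub-branches per segment. Branch lengths default to (18, 13, 13, 12, 9) mm
at the 96 mm reference size and scale with the grid. Branches that would
escape the lung are first shortened, then steered inward; irrecoverable
layouts trigger whole-tree regeneration (up to 8 attempts), after which
cramped grids are accepted with a warning.

Lobe masks are derived by nearest-lobar-subtree assignment inside each lung
— the same argmin machinery one level up — which guarantees every labeled
node lies inside its own lobe. Annotations are the first node of each
segmental branch; labels are propagated with the production operation;
ground-truth segments come from the independent exhaustive scan.

What the phantoms emulate: the topology and counts of the segmental anatomy,
lobe-constrained geometry, anisotropic distances, tracing gaps, and the
exact input/output contracts of every operation. What they do not emulate:
CT intensities and noise, real fissure geometry, anatomical variation in
branching (accessory segments, azygos lobe), breathing-state deformation,
and imperfect upstream lobe masks. Passing on phantoms therefore validates
the geometric and algorithmic machinery, not clinical accuracy on patient
scans.

At the default 96 mm / 1 mm configuration the full pipeline (generate,
parcellate, trace, evaluate) runs in a few seconds on one CPU; grids down to
32 voxels are supported for cheap randomized testing, with the caveat that
below ~64 mm the scaled branch spacing approaches the voxel diagonal, sibling
bronchi can share voxels, and the phantom is no longer strictly
self-consistent (the generator warns when this happens).

## Numerical and design choices

- 0-based voxel indexing; world <-> index mapping is diagonal; NIfTI affines
  must be diagonal up to axis flips (flips are normalized on read), oblique
  orientations are rejected. Distances are always in mm from voxel centers.
- Generation counting fixes the trachea at 0 so the main bronchi are level 1
  and segmental bronchi level 3; trifurcations are allowed and each child
  branch is one level deeper. Annotations on branches of other generations
  are accepted with a warning, since traced trees can miss a generation.
- Conflicting annotations (two segments propagating to one node) are hard
  errors, not silent overwrites.
- SWC dialect: whitespace-separated `id type x y z radius parent`, `#`
  comments, non-contiguous ids, forward parent references (two-pass read).
  Segment labels ride in the type column as `100 + code`, with JSON
  annotations as the sidecar alternative.
- Exact ties in the nearest-bronchus argmin go to the smallest segment code,
  in both the production and oracle paths.
- Outputs are float32 (scalars) / uint16 (labels) NIfTI-1; CLI writes are
  atomic (temp file + rename); exit codes are 0 / 1 (usage) / 2 (data).

## Known limitations

- No oblique-orientation NIfTI support; resample upstream if needed.
- The tracer assumes tubular probability ridges; on maps with broad plateaus
  the discrete fallback can emit slightly jagged paths.
- Segment label propagation requires a tree; a voxel-level airway lumen
  segmentation is out of scope.
- The lobe masks consumed by parcellation are inputs: errors in them
  propagate directly into segment territory, by design.
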