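# Methods

## The problem

Living architecture — root bridges, grafted-tree pavilions and other
structures grown by shaping and merging trees — forms anastomotic networks:
shoots or roots fuse, so the branching structure contains genuine loops.
Mechanical (beam) and physiological (growth) models of such structures need
a one-dimensional curve skeleton that is *topologically faithful*: every
component, every loop, and nothing else.  Photogrammetric surveys deliver a
point cloud of the visible surface; this package turns such a cloud into a
curve skeleton plus enough per-voxel shape information to rebuild the solid
volume, without ever fitting cylinders or referring back to the cloud.

## The pipeline

1. **Orientation.**  Centroid-centred PCA; the largest principal axis is
   rotated to +z (minimises the void space of the subsequent lattice).
   Eigenvector signs are fixed by requiring non-negative third moments, so
   the operation is deterministic and idempotent up to axis sign.
2. **Voxelization.**  An octree-style cubic lattice; a cell is *object*
   when at least one point falls in its half-open box.  The edge length is
   user-chosen (equivalently an octree depth: the bounding cube divided
   2^depth times per axis).  The grid is padded with one void layer so an
   external void always exists and template matching at the data boundary
   is defined (outside counts as void).  When an explicit edge length is
   given the lattice origin snaps to a multiple of it, which makes results
   translation-robust.
3. **Denoising.**  Keep the largest 6-connected object component.
   6-connectivity is deliberate: a 26-connected criterion retains diagonal
   "loose ends" that contaminate the skeleton.  A tie for the largest
   component fails loudly unless explicitly told to keep the first.
4. **Surface filling.**  Occlusion holes misrepresent topology.  Filling
   is an explicit, versionable input (a JSON fill list), not an automatic
   step; `suggest_holes` ranks void cells by object-face count (default
   threshold 4 — a one-cell puncture in a flat wall has exactly 4) as
   advice only.
5. **Internal filling.**  Flood-fill the void from the boundary with
   6-connectivity; everything unreached becomes object.  Assumes no real
   internal cavities (surface surveys cannot see them anyway).
6. **Thinning** (below).
7. **Segmentation.**  Skeleton voxels with one 26-neighbour are curve
   ends, with two are regular, with three or more are joint voxels.
   26-connected joint clusters are merged; the member nearest the cluster
   centroid becomes the true joint (ties: lowest index, logged).  Maximal
   regular chains become branches; branch geometry is the polyline of
   voxel centers, unsmoothed.  Pure loops become branches with identical
   endpoints, so the graph's cycle rank equals the object's loop count.
8. **Reconstruction** (below).

## Thinning

Sequential, directional, template-driven erosion.  Four base templates act
as directional border selectors in a 3×3×3 neighbourhood (ternary
patterns: required-void, required-object, free):

| family | constrained cells                                   | unique rotations |
|--------|-----------------------------------------------------|------------------|
| A      | void at one face, object at the opposite face       | 6                |
| B      | void at two adjacent faces + the edge between them, object at the opposite edge neighbour | 12 |
| C      | void in an open corner octant, object at the opposite corner neighbour | 8 |
| D      | object at both faces along one axis, void in a quarter-wedge orthogonal to it | 12 |

All 24 proper cube rotations, deduplicated, give 38 configurations,
applied as sub-passes in fixed order (A's 6 directions, then B, C, D).
A, B and C select border voxels with face-, edge- and corner-diagonal
support; D selects laterally exposed voxels of one-voxel plates and
columns, which have no opposite void/object face pair and would otherwise
stall.

A sub-pass candidate must match its configuration on both the current grid
and the cycle-start grid.  The cycle-start conjunction limits every cycle
to the erosion front that existed when the cycle began — exactly one shell
per direction per cycle — which is what makes the per-voxel iteration
count a radius proxy (see below).  Without it, successive orientations
cascade along thin plates several cells per cycle.

Candidates are filtered by a curve-end guard: a voxel with exactly one
26-adjacent object voxel whose sole neighbour itself has at most two
neighbours is a genuine chain end and is never deleted.  Stubs attached to
thicker material stay deletable, which suppresses spurious short branches
at eroding tube ends.

Each surviving candidate is checked against four deletion criteria:

* (a) its 26-adjacent object voxels form a single 26-connected component;
* (b) the void components of its 18-neighbourhood that touch one of its
  faces form a single 6-connected component (and at least one void face
  exists);
* (c) for any co-candidate 26-adjacent to it, some object voxel is
  26-adjacent to both (vacuous without such a co-candidate);
* (d) for any co-candidate 6-adjacent to it, two void voxels complete a
  unit square with the pair (vacuous likewise).

(a) and (b) are the local simple-point conditions — chains are not broken,
cavities are not merged; (c) and (d) arbitrate between co-candidates.
Deletions within a sub-pass are performed sequentially in sorted index
order, re-validating (a), (b) and the curve-end guard against the current
grid immediately before each deletion.  Every deletion is therefore simple
at the moment it happens, which guarantees homotopy preservation
unconditionally — including on noisy inputs, where validating only against
the sub-pass-start grid measurably breaks connectivity.  The sorted order
makes the whole loop deterministic.  The loop stops when a full cycle
deletes nothing; a guard at `2·max(dims)+8` cycles protects against
non-termination.

### Iterations of exposure

For every voxel, the cycle at which each of its six faces first became
void-adjacent is recorded (faces exposed in the input log 0).  For a
surviving skeleton voxel the four smallest values, sorted, are I1 ≤ I2 ≤
I3 ≤ I4; unexposed faces (in practice only at busy junctions) count as the
final cycle.  Because erosion is one shell per direction per cycle, on a
straight tube I1 and I2 equal the minor semi-axis and I3 and I4 the major
semi-axis of the cross-section, in voxel widths: the skeleton carries its
own local radius information.

## Volume reconstruction

**Circular mode.**  Around each skeleton voxel a filled disk of radius
`radius_scale · I_n` voxel widths is drawn in the horizontal (xy) plane;
the voxel itself is always kept (I_n = 0 rebuilds a one-voxel tube).
`radius_scale` defaults to 1.0 because one cycle erodes one shell.
Reconstruction volume is non-decreasing from I1 to I4; I2 balances
replication against redundancy for near-circular elements.

**Elliptical mode.**  The elliptical ratio ER (major/minor axis) is
predicted from the exposure ratio I4:I1 by a linear model fitted with
ordinary least squares on samples of known ER; candidate predictors
(I2:I1, I3:I1, I4:I1, and the mean (I2+I3+I4)/3 : I1) are all scored by R²
so the best can be chosen.  For n ∈ {1, 2} the minor semi-axis is
`radius_scale · I_n` and the major is ER times that; for n ∈ {3, 4} the
major semi-axis is `radius_scale · I_n` and the minor is that divided by
ER.  The major-axis direction is the in-plane cardinal direction whose
opposing faces were exposed latest (ties toward x).  Predictions are
clamped to [1, 6] — the regression extrapolates absurdly on outlier
ratios.  Voxels with I1 = 0 fall back to circular sections (counted in
the result).  Cross-sections are deliberately built in the global xy
plane stepped along z: the reconstruction is 2.5-D even though thinning
is 3-D, a known limitation inherited from the workflow design.

## Topology accounting

Topology is summarised by the Betti triple (b0, b1, b2): 26-connected
object components, independent loops, and cavities (6-connected void
components not reaching the grid boundary).  b1 is derived from the Euler
characteristic of the cubical complex (χ = V − E + F − C over the occupied
cells' vertices, edges, faces and cubes) via b1 = b0 + b2 − χ — exact and
cheap, with no explicit loop search.  The test suite cross-checks this
against an independent implementation (union-find components,
configuration-counting Euler number, BFS cavities).

## Synthetic phantoms and what they show

The phantom module generates solid tubes (circular and elliptical
cross-section), tori and Y-junctions with exact ground truth (centerline,
radius profile, Betti triple).  Surface clouds are sampled per exposed
boundary face (Poisson counts, default 24 points per face), offset along
the face normal by Uniform(±0.5) voxel widths — a half-voxel "skin" that
emulates the sub-voxel spread of real survey surfaces; an infinitely thin
face sample digitizes to the exact boundary-cell set, which on curved
tubes is not 6-connected and would be shredded by step-3 denoising even
without noise.  Gaussian coordinate noise is added with standard deviation
given as a multiple of the voxel size; occlusions are spherical-cap
cutouts about the centroid.  One seeded generator drives everything, so
all experiments are exactly reproducible.

Study geometry is fixed once: tubes use aspect ratios ≥ 6:1 (the
round-trip reconstruction phantom is a radius-4, length-48 cylinder) since
end erosion inevitably rounds free tube ends by about one radius — real
branch segments are long relative to their thickness, and surveyed
branches end at the model-space boundary rather than mid-air.  The
elliptical-ratio suite uses b = 2 and a ∈ {2, 3, 4, 6, 8} (ER 1–4),
lengths 2a + 14 so a mid-span survives end rounding.  The noise-robustness
phantom is a torus with major radius 10 and minor radius 3.

What passing phantom tests do *not* show: phantoms have analytically
smooth surfaces, uniform sampling density and no registration error;
real photogrammetric clouds have anisotropic density, large occlusions
(step-4 fill lists exist precisely for these) and bark-scale roughness
beyond the half-voxel skin.  Phantom results bound the method's behaviour
under controlled degradation; they do not certify survey accuracy.

## Numerical and degenerate-input choices

* Half-open voxel boxes: a point on a cell boundary belongs to exactly one
  cell; no double assignment.
* Out-of-grid cells are void for matching and neighbourhood queries.
* Denoise ties fail loudly by default; joint-centroid ties and
  segmentation walks break ties toward the lowest index, logged.
* PCA orientation rejects clouds with a degenerate covariance (collinear
  or coincident points) instead of guessing.
* A cylinder of radius < 1 degenerates cleanly to a one-voxel column and
  is its own skeleton.
* All randomness flows from one explicit seed per sampling spec.

## Known limitations

* Reconstruction is in-plane (xy disks/ellipses along z); strongly
  inclined branches are rebuilt with horizontal sections.
* Free tube ends erode by roughly one radius before the protected chain
  emerges; surveyed structures avoid this by extending elements to the
  model-space boundary and capping them via fill lists.
* Elements are classified circular or elliptical only; 'inverted-T' and
  'I' cross-sections are out of scope.
* Busy junctions can retain voxels with fewer than four exposed faces;
  their I values are padded with the final cycle index and flagged via
  `exposed_faces`.
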