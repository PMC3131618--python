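# Methods

## Scope and model of the data

`its-morph` analyzes 3D binary (or thresholded grayscale) volumes of
trabecular bone on an isotropic grid, with `z` the longitudinal axis. The
intended regime is HR-pQCT-like imaging: 82 µm voxels, trabecular
thickness 0.1–0.3 mm (1.5–4 voxels), bone volume fraction 0.05–0.3. The
pipeline assumes a pre-extracted trabecular cube; periosteal contouring
and cortical/trabecular separation are upstream of this package.

## Image preparation

The scanner's segmentation chain is an edge-enhancing filter followed by a
global threshold at 40% of the volume's maximal gray value. The filter's
manufacturer constants are not public, so the implementation is a
frequency-domain Hamming-windowed low-pass multiplied by a weighted
Laplacian term, `T(ρ) = W(ρ)·(1 + w·(ρ/0.5)²)` with `W` a Hamming window
cut at `cutoff` cycles/sample (default 0.4) and `w = laplace_weight`
(default 0.5). `T(0) = 1`, so flat regions are preserved. Both parameters
are recorded in output metadata, and the pipeline accepts pre-thresholded
binary input directly, so all downstream morphology and stiffness results
are independent of the filter choice. Thresholding uses an inclusive
comparison (`≥ fraction·max`) for determinism on integer-valued synthetic
data; the maximum is taken over the volume passed in.

## Skeletonization

The skeleton is produced by iterative deletion of *simple points* —
voxels whose removal changes neither the number of 26-connected
components, nor tunnels, nor cavities — using the standard (26, 6)
foreground/background connectivity pair. Simplicity is decided locally
from two numbers on the punctured 3×3×3 neighborhood: `A`, the number of
26-components of foreground, and `B`, the number of 6-components of
background within the 18-neighborhood that touch a face neighbor; a voxel
is simple iff `A = B = 1`. Deletion is sequential (each removal
re-validated), distance-ordered (outermost first by Euclidean distance
transform) with a fixed raster tie-break, so the result is deterministic.

Shape preservation uses two alternating phases run to a joint fixed
point:

1. *Surface-preserving thinning.* Never delete curve ends (≤ 1 neighbor)
   or voxels of 1-voxel-thick sheets. A voxel counts as a sheet voxel
   when it is thin along some axis (both axis neighbors background) and
   its co-thin neighbors span two non-collinear directions; this protects
   flat and tilted sheets including their edges, while the convex rims of
   still-thick bodies keep eroding.
2. *Curve thinning.* Structures that end phase 1 as 2–3 voxel wide
   ribbons (near-cylindrical struts; the small medial "webs" left where
   struts cross) are reduced to 1-wide curves. Genuine sheets are
   shielded: connected regions of `B ≥ 2` voxels whose cores are locally
   two-dimensional (core neighbors spanning non-collinear directions) and
   at least `min_sheet_voxels` large (default 12 ≈ 0.08 mm² of sheet
   core), dilated by one voxel to cover sheet edges.

Because every protection rule is a function of the current volume only,
the final skeleton is a fixed point: re-skeletonizing a skeleton is the
identity. Topology preservation is guaranteed per deletion by the simple
point test and is additionally verified in the test suite against an
independent Euler-characteristic oracle.

Each skeleton voxel is then classified from (`A`, `B`, neighbor count):
isolated, curve end/interior, surface interior/edge, and junction
subtypes. Two configurations are invisible to (`A`, `B`) at 3×3×3 scale
and are handled explicitly: in-plane branch points (arms of a T or X
interconnect diagonally around the branch voxel), detected as curve
voxels with ≥ 3 skeleton neighbors — valid because thinning leaves no
redundant corner voxels — and in-plane curve crossings, which look like a
tiny sheet and are resolved at segmentation time (below). Junction
clusters are typed by what they join: surface-surface, surface-curve, or
curve-curve.

## Individual-trabeculae segmentation

Junction voxels delimit segments. Labeling of surface and curve voxels
uses junction-aware connectivity: an adjacency between two voxels is
dropped when they are not face-adjacent and both touch the same junction
voxel — otherwise the arms meeting at a junction would fuse by wrapping
diagonally around it.

Surface components must look like plates to count as plates: second
principal extent at least `min_plate_width` voxels (default 3) *and* at
least `plate_aspect` times the local thickness (default 2 — a plate is at
least twice as wide as thick). Failing patches touching ≥ 3 curve arms
act as junctions (the in-plane crossing case); the rest are rod-like
ribbons. At junctions joined only by rods, near-collinear arm pairs
(angle within `merge_angle_deg`, default 30°, arm directions estimated by
principal-axis fits of the arm voxels nearest the junction) are merged:
a rod passes through a junction. Segments below `min_segment_voxels`
(default 2) are absorbed into their largest neighbor. Junction voxels are
counted separately for junction densities but assigned to the adjacent
segment with the largest contact so the partition stays exhaustive.

Every bone voxel is then claimed by exactly one trabecula via multi-source
Dijkstra growth restricted to the bone mask (26-connected, Euclidean step
weights), i.e. geodesic distance — labels cannot jump across marrow
space. Ties resolve to the smaller distance, then the lower segment ID.
The partition property (plate voxels + rod voxels = bone voxels, exactly,
in integer counts) holds by construction and is asserted over a 30-volume
battery.

Per-trabecula measures: volume = voxel count × h³; thickness = 2 × mean
Euclidean distance transform over the trabecula's skeleton voxels − 1
voxel (distances are center-to-center, so the two half-voxel overhangs are
subtracted), floored at one voxel; plate surface area = sheet voxel count
× h²; rod length = longest geodesic path through the segment's skeleton
(double-sweep Dijkstra, exact on chains) + 1 voxel so both endpoints
count; orientation = smallest (plate normal) or largest (rod axis)
principal component of the skeleton voxel cloud.

## ITS parameters

With `TV` the examined volume and `h` the voxel size: `pBV/TV`, `rBV/TV`
are plate/rod voxel volumes over TV (their sum is BV/TV exactly);
`pBV/BV`, `rBV/BV` the tissue fractions (sum to 1); `pTb.N`, `rTb.N` the
cube roots of count per volume, the only reading of a count-per-volume
quantity with the printed unit 1/mm and 1–2/mm magnitudes; `pTb.Th`,
`rTb.Th` bone-volume-weighted mean thicknesses; `pTb.S` the mean area per
plate; `rTb.ℓ` the mean rod length; junction densities are junction
clusters per mm³ counted on the 1-voxel skeleton, by subtype. `aBV/TV` is
the volume of axial trabeculae over TV: a rod is axial when its axis is
within 30° of `z`, a plate when its plane contains `z` within 30° (cone
half-angle configurable). `pTb.S` is reported as the mean area per plate,
consistent with mm² units at ~0.14 magnitude; the per-volume total is
recoverable as `pTb.S · (pTb.N)³ · TV`.

## Micro-finite-element homogenization

One 8-node trilinear hexahedron per bone voxel, all sharing one isotropic
tissue material (default `E_t` = 15 GPa, ν = 0.3; every output modulus is
proportional to `E_t`, so anisotropy ratios are tissue-modulus-free). The
element stiffness uses 2×2×2 Gauss quadrature, which is exact here. Six
analyses — three uniaxial strains, three shears — are imposed as
kinematic uniform-strain displacement boundary conditions `u = E·x` on
all nodes of the domain boundary; this yields the full 6×6 apparent
stiffness (Voigt order [11, 22, 33, 23, 31, 12], axes 1, 2, 3 = x, y, z)
from exactly six solves, as an upper-bound-type estimate. The interior is
solved matrix-free by element-by-element conjugate gradients with a
Jacobi preconditioner (relative residual 10⁻⁶ by default); columns are
mean element stress over the full examined volume divided by the applied
strain, and the matrix is symmetrized. 26-connected components that do
not touch the domain boundary cannot be loaded and are removed (volume
logged); a mask that does not span an axis triggers a warning.

The best orthotropic coordinate system minimizes the squared norm of the
stiffness entries that vanish under orthotropy (the 3×3 normal-shear
coupling block and the shear-shear off-diagonals) normalized by ‖C‖²,
over three Euler angles, with ≥ 8 Powell starts on an angle grid;
degenerate (isotropic or already-orthotropic) inputs return the identity
by tie-break. Engineering constants come from inverting the decoupled
orthotropic stiffness; axes are relabeled so `E11 ≤ E22 ≤ E33` with the
shear moduli permuted consistently (`G23` couples the new axes 2 and 3).

## Statistics

Mann-Whitney U is two-tailed: exact (dynamic-program null distribution of
the rank sum; p = twice the smaller tail, capped at 1) when the pooled
sample is ≤ 20 without ties, otherwise the normal approximation with tie
correction and no continuity correction. Correlations are product-moment
with flags at p < .001/.01/.05. Partial correlation uses the first-order
identity and is verified in tests to equal the residual-regression route
to 10⁻¹². Forward stepwise regression enters, at each step, the candidate
with the smallest partial-F p-value (equal to the squared-t test for a
single added variable) while it is below `alpha_enter` (default 0.05;
0.1 is a useful preset when reproducing tables that retain predictors up
to p < .1); it reports entry order and the adjusted correlation
coefficient √(max(adj R², 0)). Percent differences between group means
are rounded half away from zero.

## Synthetic data

Phantoms are rasterized from analytic solids — finite oriented slabs and
finite cylinders — by voxel-center containment, so ground-truth volumes
are exact and orientation-independent; with overlaps, ground-truth
ownership goes to the solid whose surface is deepest (mirroring the
reconstruction tie-break). The realistic generator
(`make_trabecular_phantom`) builds a staggered, per-node-jittered strut
network spanning the grid (so subvolume faces cut struts, as cropping a
real trabecular cube does and as the FE boundary conditions require),
plus a few vertical plates. Defaults — node spacing 9 voxels (0.74 mm),
rod radius 1.3 voxels (diameter 0.21 mm), plate thickness 2.3 voxels
(0.19 mm), vertical-strut probability 0.8, in-layer strut probability
0.35, node jitter ±1 voxel — give BV/TV ≈ 0.12–0.19, rod number density
≈ 1.3–1.5/mm, rod length ≈ 0.5 mm, thicknesses ≈ 0.1–0.12 mm at 82 µm
voxels. The staggering makes struts meeting at a node genuinely
non-collinear, so rods terminate at junctions as they do in real bone.

Degradation removes whole trabeculae with a given probability and
re-rasterizes the survivors from the analytic spec: survivor thickness is
untouched by construction. This emulates the deterioration pattern in
which the network loses trabeculae and connectivity without thinning.

What the phantoms do not emulate: curved and tapered trabeculae, surface
roughness, partial-volume gray levels, marrow inhomogeneity, cortical
remnants, and scanner noise. Passing the synthetic suites therefore
demonstrates correctness of the algorithms under exactly known geometry,
not clinical accuracy on scans.

## Numerical choices and degenerate inputs

All tie-breaks (thinning order, reconstruction claims, junction
assignment, ID relabeling) are deterministic; identical input and
configuration give identical outputs, byte-for-byte in the pipeline
files. Empty masks yield empty skeletons and all-zero metrics (with a
warning); empty FE masks and all-zero grayscale volumes are errors.
Anisotropic voxel headers are rejected rather than resampled. CG failure
to converge raises rather than returning a partial stiffness.

Problem sizes in the shipped tests and the acceptance script — ≤ 32³
volumes for topology batteries, ≤ 12³ FE models for direct-solve
cross-checks, 48³ for end-to-end cohorts of 20 + 20 — were chosen so the
whole suite runs on a single CPU in minutes while leaving every
asymptotic property (partition, topology preservation, scaling,
significance of the dropout signature) measurable.

## Known limitations

* At 82 µm, struts are 2–3 voxels thick; the medial web where struts
  cross is genuinely two-dimensional, and where several struts meet
  densely or run close and parallel, such webs can survive as small
  "plates". This inflates the plate tissue fraction of rod-dominated
  networks relative to the analytic truth (the same partial-volume regime
  in which junction parameters of real scans are known to be least
  reliable). Group *contrasts* under dropout are robust to this, but
  per-subtype junction densities can migrate between subtypes when webs
  disappear; the cohort checks therefore also use the total junction
  density.
* The digital thickness estimator (2·EDT − 1) is exact for odd
  axis-aligned thicknesses and biased low by up to one voxel for even or
  oblique structures; recovery tests use the half-voxel rasterization
  bound accordingly.
* Kinematic uniform-strain boundary conditions are an upper-bound-type
  estimate of apparent stiffness; periodic or mixed conditions are not
  implemented.
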