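# Methods

`enthemorph` re-implements, as a tested pipeline, a 3D micro-CT morphometry
workflow for bone and mineralized fibrocartilage near a tendon insertion
(enthesis): spatially resolved trabecular fabric, subchondral-channel network
morphometry, fibrochondrocyte-lacuna morphometry, mineralization-front
roughness, and the accompanying statistics.  Because no real scans ship with
the package, every stage is validated on synthetic phantom volumes with
exactly known ground truth; this note records the models, the parameter
choices, and what the phantom validation does and does not establish.

## Coordinate and orientation conventions

Volumes are indexed (x, y, z) with x cranio-caudal, y dorso-plantar and z
medio-lateral; the sagittal plane is XY.  Undirected axes (channels, lacuna
long axes, fabric eigenvectors) are reported as a polar angle θ from +z and
an azimuth ϕ of the XY projection from +x, mapped onto the half sphere
0° ≤ ϕ < 180° so that an axis and its negation are identical.  Vectors
parallel to z have no defined azimuth and are flagged.  Components below
1e-12 after normalization are snapped to zero so boundary vectors
canonicalize consistently.

## Preprocessing

Grayscale volumes are smoothed with a 3D Gaussian (sigma 0.65 voxels on a
3×3×3 support by default; a wider support is available via
`support_radius`), with reflective padding so face voxels are not darkened
before thresholding.  Binarization uses a global Otsu threshold implemented
as an exact exhaustive maximization of between-class variance over candidate
gray levels (all distinct values; 256 quantized levels for near-continuous
data), with the lowest maximizing threshold on ties and threshold-equal
voxels assigned to background.  Alignment rotates the segmented bone onto
its principal axes of inertia (long axis → x) with nearest-neighbour
resampling to preserve binarity; a near-spherical inertia tensor returns the
identity with a degeneracy flag.  Because rotation resamples a discrete
grid, the aligned inertia tensor is diagonal only to ≈1 % of its trace, not
to machine precision.

The bony protrusion (tuberosity) is delimited per sagittal slice from the
plantar surface-height profile: the protrusion is the rise of ≥ 2 voxels
above the fitted flat contour, retained when its ascending flank makes an
angle of at least 100° with the flat periosteal surface (180° = flat,
90° = cliff).  The 2-voxel end criterion is the computable surrogate for
the visual "no protrusion evident anymore" rule.

Marching cubic VOIs have 0.75 mm side and 0.375 mm step (half-side
overlap); side and step must be whole numbers of voxels, and cubes that
would contain non-region voxels are not emitted.

## Trabecular and fabric analysis

BV/TV is the foreground voxel fraction.  Tb.Th and Tb.Sp use sphere-fitting
local thickness (largest inscribed sphere covering each voxel), computed by
sweeping sphere radii in half-voxel steps over the Euclidean distance
transform.  The EDT is offset by +0.25 voxel: the physical boundary lies
half a voxel beyond the background centre for face contacts but pokes
inward for diagonal contacts, and the quarter-voxel compromise keeps both
slab and cylinder phantoms within one voxel of truth.  The volume faces are
treated as neither phase, so structures cut by a face read as continuing;
phantoms used for thickness validation keep the measured phase interior.

The fabric tensor is fitted from mean intercept lengths: deterministic
low-discrepancy (Fibonacci) directions on the hemisphere (default 512),
each carrying a parallel test-line grid (4-voxel spacing, 0.5-voxel
sampling) with a seeded random lateral offset.  Background gaps shorter
than 1.5 voxels along a line are closed before counting intercepts; without
this, staircase jags on oblique interfaces create spurious sub-voxel
intercepts and the measured anisotropy loses its rotation invariance (the
plate-phantom DA spread across random lattice orientations drops from
≈0.3 to <0.05 with the correction).  MIL(ω)⁻² is fitted by least squares
with the quadratic form ωᵀHω; the fabric eigenpairs are those of H with
λ₁ ≥ λ₂ ≥ λ₃.  This is the one convention consistent with both reported
limits — DA = 1 − λ₃/λ₁ giving 0 for isotropic and 1 for fully anisotropic
fabrics — and with the preferred orientation being the eigenvector of the
smallest eigenvalue (the direction of the longest intercepts, i.e. along
the trabeculae or in-plane for plates).  Preferred orientations of fabrics
with DA < 0.05 are flagged unreliable.

## Channel network

Channel extraction follows the protocol: erode a 125 µm surface layer
(implemented as an EDT threshold, so the depth must be a whole number of
voxels), keep the largest solid object, invert, remove 2D cross-section
objects smaller than 20 px per slice (≈6 µm equivalent diameter at 1.25 µm
pixels; a 3D variant is available behind a flag), and keep the largest
connected pore component.  Pore components touching the volume border are
treated as exterior space.

Skeletonization is an in-house Euclidean distance-ordered sequential
homotopic thinning: six directional subiterations per pass, candidates
processed in order of increasing EDT with a lexicographic tie-break (so
one-voxel sheets peel line by line instead of collapsing), deletion
restricted to simple points (Bertrand–Malandain criterion — one foreground
26-component in the neighbourhood and one background 6-component touching a
face — evaluated through a bit-packed configuration cache), and curve
endpoints preserved.  Components and loops of the pore space are preserved
exactly (verified by component counts and Euler numbers on tube and torus
phantoms).  Each skeleton voxel retains the EDT value as the local channel
radius.

Skeleton voxels with ≥ 3 skeleton neighbours (26-connectivity) are grouped
into junction nodes; connected components of the remaining voxels are
channels.  Channel length is the smoothed polyline length of the ordered
path (5-voxel moving average of the coordinates; the raw voxel path zigzags
around the medial curve and overestimates oblique channel lengths by up to
~15 %).  Free ends are first trimmed of spurs whose radius profile shrinks
outward (thinning occasionally runs a spur into the rounded pore cap) and
then extended along the end tangent for as long as the distance map keeps
the local radius, compensating endpoint retraction.  Channel diameter is
twice the mean per-voxel radius; connectivity counts distinct other
channels incident to either endpoint junction; orientation is the canonical
axis of the endpoint-to-endpoint vector (principal axis for closed loops).
Aspect-ratio classes follow ρ = Ch.Dm/Ch.L with thick ρ ≥ 1, slender
0.1 < ρ < 1, extremely slender ρ ≤ 0.1 (boundaries assigned per the printed
inequalities).  Channels shorter than 2 voxels are dropped and counted.

On non-intersecting tube phantoms (radii ≥ 4 voxels) this recovers
per-channel orientations with a mean absolute error below 1°, lengths
within ~2 voxels and diameters within ~1 voxel.

## Lacunae

Pores of the fibrocartilage layer are labelled (26-connectivity); objects
with volume in [1000, 30,000] µm³ are lacunae or lacuna aggregates; the
upper bound keeps aggregates while excluding channel-sized objects, and no
splitting of aggregates is attempted.  Border-touching components are
flagged and excluded by default (replacing manual removal of channel parts
entering the region).  Sphericity is the area of the volume-matched sphere
over the object's surface area, with the surface measured on a
marching-cubes mesh of the slightly smoothed indicator (sigma 1 voxel):
raw voxel-face or raw-mesh areas overestimate smooth surfaces, keeping
sphericity of true spheres near 0.93, while the smoothed mesh converges to
1 within 2 % for radii ≥ 16 voxels (values are clamped at the physical
bound 1).  Orientation is the principal axis of the voxel second-moment
tensor; objects with long/short axis ratio < 1.1 are flagged unreliable.
Orientation statistics are restricted to elongated pores (L.Sph < 0.6),
applied after segmentation and only for orientation analyses.  Size classes
default to tertiles of the volume window.

## Interface roughness

Within a rectangular mask (437.5 µm × 625 µm at 1.25 µm pixels) the
mineralization-front contour is the topmost foreground transition per
column; masks whose profile is multi-valued in more than 5 % of columns
(e.g. a vessel opening) are excluded with a reason.  A least-squares
5th-order polynomial is the reference line (capturing overall shape without
absorbing local roughness); surface heights are shortest Euclidean
distances from contour points to the densely sampled reference curve
(0.1-pixel steps, verified never to exceed vertical distances), and Pq is
their root mean square.  The study bookkeeping (5 samples × 10 sections
≈ 30 µm apart × 3 regions = 150 masks) is reproduced by the mask scheduler.
A threshold-sensitivity sweep re-measures Pq at relative threshold offsets,
skipping offsets that collapse a phase.

## Statistics

Scalar group comparisons use Student's t test when both samples pass a
Kolmogorov–Smirnov normality check and a two-sided F test for equal
variances at alpha = 0.05, otherwise Mann–Whitney U; the normality check
defaults to the estimated-parameter (Lilliefors) variant since parameters
are never known a priori, with the naive variant behind a flag.  Fully tied
samples short-circuit to p = 1 (no evidence of difference under
exchangeability).

The two-sample two-dimensional Kolmogorov–Smirnov statistic D is the
maximum over the four quadrant orientations, anchored at every pooled data
point, of the absolute difference in empirical quadrant probabilities, with
quadrant boundaries closed on the evaluated point (deterministic tie
handling).  It is verified against brute-force enumeration.  The default
p-value comes from 2000 label permutations of the pooled sample (vectorized
through quadrant-membership matrices); because D is discrete the reported p
is the standard conservative permutation p, and the mid-p (half weight on
ties) is exposed in the report metadata as the calibrated diagnostic — the
mid-p is uniform under the null while the reported p rejects at most alpha.
A classical large-sample approximation (correlation-corrected effective-n
KS tail) is available and agrees with permutation in its advertised
small-p regime.  Angles enter as raw (θ, ϕ) pairs on the canonical
hemisphere with no toroidal wrap correction — a known limitation shared
with the original use of the test.

## Phantom generators

All objects are rasterized by evaluating their analytic inequality at voxel
centres (no anti-aliasing), so voxel counts converge to analytic volumes
(within 5 % for radii ≥ 4 voxels) and regeneration from the same seed is
bit-identical.

* **Tubes** are capsules (segments with radius) carved from a solid plate;
  axes are fixed, drawn around a mean axis with a small-angle Gaussian
  tangent-plane dispersion (degrees), or isotropic; children may branch
  from a parent axis; optional capsule-to-capsule separation produces
  non-intersecting sets with unambiguous per-channel truth.  Radii below
  2 voxels are rejected as unresolvable.
* **Lacunae** are prolate ellipsoids (default 2.5:1) or, with
  `aggregate_size` > 1, chains of partially overlapping ellipsoids forming
  corrugated columnar aggregates — the only way to reach the L.Sph < 0.6
  regime of the orientation analysis, since single prolate ellipsoids stay
  above ≈0.6 sphericity even at 10:1.  The aggregate tests use 3.5:1
  ellipsoids in chains of five (a plausible fibrochondrocyte column),
  giving sphericities of ≈0.58.  Objects never overlap (capsule distance
  checks); volumes stay inside the 1000–30,000 µm³ analysis window; the
  rasterized volume of each object is recorded as its ground truth.
* **Trabecular lattices** are parallel plates (anisotropic, DA → 1) or
  cubic-symmetric square-section rods (isotropic, DA → 0) with analytic
  volume fractions (t/p and 3a²−2a³); thickness and spacing default to
  100 µm, the scale of rat calcaneal trabeculae.  A linearly graded plate
  spacing (cumulative-phase construction, local fraction exactly
  thickness/period) provides known BV/TV gradients; a lattice phase offset
  keeps measured phases away from volume faces.
* **Interfaces** are 2D binary images whose boundary is a 5th-order
  polynomial baseline plus correlated Gaussian roughness (Gaussian kernel
  of the prescribed correlation length, default 15 µm), detrended by its
  own 5th-order fit and rescaled to the target RMS exactly.  Correlation
  lengths below 3 pixels or above a fifth of the mask width are refused
  (unresolvable, or absorbed by the reference polynomial).
* **Degradation** is Gaussian blur followed by additive Gaussian noise
  scaled to the foreground–background contrast; noise must stay below 0.5
  so a global threshold remains recoverable.  At 10 % noise the filtered
  Otsu segmentation agrees with the clean mask on ≥ 99 % of voxels.

What the phantoms do not emulate: polychromatic X-ray physics (beam
hardening, ring artifacts, partial-volume blur beyond a Gaussian), real
pore-surface texture, curved channels, or biological variability between
specimens.  Passing the suite therefore establishes correctness of the
measurement chain on resolvable geometry, not scanner-specific accuracy.

## Problem sizes and numerical choices

Validation volumes are 96³–240×160×160 voxels with feature radii of 4–12
voxels, chosen so every stage's ground-truth recovery runs in seconds to a
couple of minutes on one CPU while keeping features comfortably above the
2-voxel resolvability bound.  The permutation count defaults to 2000 with
the seed recorded in the report; the acceptance checks use 500 null
replicates at 1000 permutations.  Ties, degenerate inputs and error paths
(constant volumes, empty phases, zero vectors, rank-deficient fits,
collapsed thresholds) raise or flag explicitly rather than returning silent
defaults.

## Known limitations

* Global metrics inherit a ≈half-voxel surface-position ambiguity; local
  thickness is accurate to ±1 voxel by construction.
* The thinning is sequential and order-dependent; different (deterministic)
  tie-break orders can move individual skeleton voxels by one position,
  though topology and the tested morphometric tolerances are unaffected.
* The 2D KS test treats the angular domain as a plane; axes near the ϕ wrap
  at 0°/180° are split, which is conservative for detecting differences
  between smooth orientation distributions.
* Face-touching structures read as continuing beyond the volume in
  thickness analyses; analyses of real scans should crop VOIs so the
  measured phase is interior, as the phantoms do.
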