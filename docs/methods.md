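# Methods

This note documents the models and procedures implemented in `gasig`, the
parameters that matter, the synthetic data they are validated on, and the
limits of what those validations show.

## Ratiometric signaling readout

The biosensor couples a GA-degradable sensor fluorophore to a
GA-insensitive reference fluorophore expressed stoichiometrically from the
same transcript. Per nucleus the package reports

    signaling S = 3 − V/B,

with `V` and `B` the background-subtracted mean sensor and reference
intensities over a sphere (default radius 2 µm) around the detected
centroid. The offset 3 spans the ratio range observed for such sensors, so
S runs from ≈ 0 (no GA signaling, sensor fully stabilised) to 3 (sensor
fully degraded). Values outside [0, 3] are reported unclipped and flagged
(`out_of_range`): they indicate miscalibration, and clipping would hide
that. For comparisons against constitutive control lines,
`standardize_ratios` divides each image's ratios by their mean so that
distributions are centred on 1.

Detection runs on the reference channel, which is present in every nucleus
regardless of signaling level, so detection cannot bias the sampled
signaling distribution. The stack is linearly resampled onto an isotropic
grid (default 1 µm) aligned with the physical origin; blobs come from a
multi-scale Laplacian-of-Gaussian (scales 1.0–2.5 µm, matching nuclear
radii), are merged below a 2.5 µm separation, and are refined by an
iterated local intensity centroid, which brings centre errors well below
half a voxel. Background per channel is a percentile (default 5th) of the
non-tissue voxels (below Otsu of the smoothed wall channel); records whose
reference mean falls below `min_reference` (default 3× the background
median absolute deviation) are dropped and counted in the QC log, because
the ratio of two dim signals is unstable.

## Cell segmentation and surface geometry

Cells are segmented from the wall-stain channel with a seeded 3D
watershed. The tissue mask is Otsu on the Gaussian-smoothed (1 µm) wall
signal with a small closing; holes are deliberately not filled, because a
single-layered dome encloses a stain-free cavity. Seeds are h-minima of
the smoothed wall (depth 5% of the dynamic range) inside the mask eroded
by 1.5 µm. The erosion matters: thresholding overshoots the true surface
by roughly the smoothing scale, and that thin, connected rind of stain
bleed would otherwise let basins crawl over the outer surface into
neighbouring cells. The watershed therefore floods only the eroded core;
the rind is re-attached per label, first along the optical axis
(consistent with the package's top-down projection conventions) and then
by 3D nearest distance. Labels are renumbered in centroid order so
repeated runs are bit-identical.

On 50-cell synthetic domes sampled at 0.3 µm in-plane (a typical confocal
Nyquist pitch; 1 µm optical sections) this yields ≥ 95% voxel agreement
with ground truth under best bipartite label matching; the residual
disagreement is concentrated within half a pixel of the true wall
midline, where assignment is genuinely ambiguous at the voxel level.

L1 cells are those exposing at least 3 µm² of the top tissue surface (the
first tissue voxel per column seen from above). Surface curvature uses the
same height map: after Gaussian smoothing (2 µm) the mean curvature
follows the Monge-patch formula, signed so an upward-convex dome is
positive, and is averaged per cell away from a 3 µm rim margin. A sphere
cap of radius R recovers 1/R within 10% across R = 20–100 µm, which pins
the convention regardless of the mesh details. The meristem radius is the
mean top-down distance from the SAM surface centre (centroid of surface
vertices, or an expert override) to the two incipient primordia I1/I2.

## Registration, lineage, growth

Consecutive stacks are registered rigidly with rotation restricted to the
optical axis — dissected meristems are re-mounted approximately upright.
The rotation is found by a coarse-to-fine grid search (1°, then 0.1°)
scoring the normalised correlation of z-mean projections; mean rather than
max projections, because the bright outer surface saturates a max
projection into a featureless disc that carries no rotation signal. The
final 3D translation comes from sub-voxel phase correlation at the chosen
angle. On synthetic drifts (≤ 5 µm translation, ≤ 10° rotation) recovery
is within one voxel and well under 1°; a normalised-correlation floor
(default 0.2) turns failed alignments into errors rather than silent
nonsense.

Lineages assign each later cell to the earlier cell with maximal voxel
overlap after registration, with a CSV override hook for expert
corrections. Overlap tracking is reliable under drift alone; under strong
radial growth, rim cells move by about a cell diameter per 10 h interval
and overlap tracking degrades — which is why growth maps in curated
analyses use expert lineages, and the package's growth validation does the
same (ground-truth lineages stand in for the expert).

Growth is measured on projected (top-down) cell footprints:

    growth intensity = (A₂ − A₁) / (A₁ Δt)   [h⁻¹],

with A₂ summed over children (a log variant is exposed). Anisotropy
compares principal second moments of the parent footprint (mapped through
the registration transform) and the children's union: with stretch ratios
s₁ ≥ s₂ from paired eigenvalue ratios, anisotropy = (s₁−s₂)/(s₁+s₂) and
the principal direction is the leading child eigenvector. Pairing
largest-with-largest makes pure rotation score 0; a two-fold uniaxial
stretch scores 1/3. A junction-point (three-wall meet) estimator was
considered and not adopted: junction correspondence across frames needs
neighbour-identity bookkeeping that curated data does not provide, and the
moment estimator meets the package's recovery targets (per-region mean
growth within 10%, anisotropy within 0.05, ≥ 30 cells per region).

## Division-plane orientation

New walls are the shared boundaries of the two daughters in the top-down
projection, skeletonized and ordered into a polyline. For parents with
more than two children (two division rounds in one interval), walls are
recovered by greedy sibling merging: the pair of child groups with the
longest shared boundary is the most recent division; it is emitted and
merged, so k children give k−1 walls. The wall direction is a
total-least-squares line fit to the skeleton (robust to curved skeletons;
an endpoint-chord variant is exposed); the angle to the radial axis
(SAM centre → wall midpoint) is folded to [0°, 90°], where 90° is
circumferential/transverse. Frequencies use nine right-open 10° bins with
the last bin closed, so fully transverse 90° events are counted.
Angles are measured in the top-down projection by default (a tangent-plane
variant would require mesh normals and is out of scope); region classes
(CZ within the CZ radius; P inside annotated primordium discs; IPR
otherwise) come from user annotations or generator truth — automatic
primordium detection is deliberately not attempted.

## Atlas and statistics

Samples are aligned by translating the CLV3-domain centroid to the origin
and rotating the annotated reference primordium to azimuth 0 — the CLV3
domain is rotationally symmetric, so translation alone cannot superpose
primordium patterns. Aligned per-cell observations are averaged,
unweighted across cells of all samples, on a polar grid (default 2 µm ×
5°); empty bins are masked, never zero-filled. Spearman, Kolmogorov–
Smirnov, Welch and Kruskal–Wallis delegate to scipy's vetted routines
behind thin contract-enforcing wrappers (the test suite checks them
against brute-force rank and ECDF oracles); PCA is computed directly from
the SVD of z-scored variables with a deterministic sign convention (each
loading's largest-magnitude entry positive).

## The synthetic generator

`gasig.synthgen` renders what the analysis assumes, with full ground
truth, and is the package's test bed:

* **Geometry.** The L1 is a 6 µm shell on a spherical cap (default radius
  30 µm, cap half-angle 50°). Cells are vertical prisms over a relaxed
  (sunflower-seeded, Lloyd-iterated) Voronoi tessellation of the projected
  cap disc; the default density gives ≈ 5 µm cells, matching SAM
  epidermis. An optional filled interior adds deeper cells for watershed
  realism. Primordia are discs whose radius grows with stage
  (4 + 1.5·stage µm).
* **Channels.** Nuclei are 3D Gaussian blobs (σ = 1.5 µm) with
  stoichiometric amplitudes `sensor/reference = 3 − S(region)` — the
  inverse of the readout, so signaling-field recovery is a round-trip
  test. Defaults follow the biological pattern: S = 2.5 in the IPR, 1.8 in
  the CZ, 1.0 in primordia. The wall channel is an inverse-distance ridge
  on label boundaries, rendered on tissue voxels only; the stem-cell
  domain channel decays as a Gaussian of the distance to the dome axis.
  Additive Gaussian noise (default σ = 2 on gains of 100–200) and optional
  Poisson noise are applied last; identical spec + seed is bit-identical.
* **Growth.** Frames are related by a radial area map in the projection
  plane whose local area factor is piecewise constant (CZ rate inside the
  CZ radius, peripheral rate outside; defaults 0.01 and 0.03 h⁻¹ over
  10 h intervals — slow centre, faster periphery). The dome radius
  inflates with the cap so geometry stays valid over many frames. Ground
  truth records the imposed per-cell area ratio and stretch anisotropy by
  integrating the map Jacobian over each cell's footprint, since cells
  straddling the CZ boundary genuinely grow at a mixture of the two rates.
  A primordium-specific rate cannot be imposed by a globally consistent
  radial map, so P cells inherit the peripheral rate; recovery tests
  compare against the recorded per-cell truth.
* **Divisions and drift.** A stated fraction of cells (default 15% per
  10 h interval) divides; the daughter wall passes through the parent
  footprint centroid at an angle to the local radial direction drawn from
  a per-region von Mises law (mode, concentration κ; κ = 0 uniform, κ → ∞
  degenerate), folded to [0°, 90°]. The defaults bias the IPR strongly
  transverse (mode 90°, κ = 4) and other regions weakly. A rigid drift
  (≤ 5 µm in-plane, ≤ 1 µm axial, ≤ 10° about z) is applied and recorded
  per interval — enough to exercise registration without destroying
  overlap-based lineage.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical anisotropy of the PSF, depth-dependent
attenuation and bleaching, chromatic shifts, curved anticlinal walls
(generator cells are vertical prisms, so the projection-based footprint
measurements are exact by construction), primordium bulging out of the
dome, and non-rigid tissue deformation between mountings. Results on real
stacks depend on acquisition quality in ways these tests cannot certify.

## Validation scenarios and problem sizes

The test battery runs on desk-scale scenes chosen to keep each check
statistically meaningful: a 50-cell noiseless dome for the signaling round
trip (per-region means within 1%); a 50-cell dome at 0.3 µm in-plane pitch
for voxel-level segmentation scoring (≥ 95%); a 300-cell, two-frame
time-lapse sized so CZ, IPR and P each hold ≥ 30 cells for growth
recovery; a four-frame, 200-cell series accumulating > 200 division events
for the angle-distribution KS check (below the α = 0.01 critical value);
and two four-plant "genotypes" (transverse bias everywhere vs IPR-only)
pooling ≈ 400 events each, which reproduce the expected ordering of the
80–90° frequency. Division-frequency recovery is checked against the
binomial interval of the imposed fraction.

## Known limitations

* Watershed accuracy is quoted at 0.3 µm in-plane sampling; at 0.5 µm the
  same pipeline scores ≈ 91%, limited by genuinely ambiguous wall-midline
  voxels rather than by topology errors (cell counts stay exact).
* Overlap lineage tracking assumes displacements small relative to cell
  size; strong growth requires curated lineages (supported via the
  corrections file).
* The atlas alignment is rigid; no deformable registration is attempted,
  so sample-to-sample shape variation widens atlas bins rather than being
  corrected.
* Whether multi-sample averaging should weight plants equally rather than
  cells equally is left as the simpler per-cell mean; with balanced
  samples the two agree.
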