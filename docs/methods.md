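# Methods

This note documents the models, conventions and numerical choices behind
`chromdom`, stage by stage, including what the synthetic-data generator
does and does not emulate.

## Coordinate and unit conventions

All arrays are indexed 0-based as `(z, y, x)`. Physical spacing is carried
as `(spacing_z, spacing_xy, spacing_xy)` in micrometres; the acquisition
defaults are 0.06 µm in-plane and 0.15 µm between Z-slides, as produced by
SIM reconstruction. Intensities are camera counts (non-negative integers)
on input and floating point after enhancement. CSV outputs state units in
a header comment.

## Z enhancement

Two slides are inserted between each adjacent pair of real Z-slides. At
inserted positions 0.05 µm and 0.10 µm into a 0.15 µm gap, the
distance-weighted average Î = (2/3)·I_near + (1/3)·I_far is exact linear
interpolation, so a stack whose intensity is affine in z is reproduced
exactly, and every interpolated voxel is a convex combination of its two
real neighbours. For N real slides the output has 3N−2 slides flagged
`real, interp, interp, real, …` at a 0.05 µm pitch. Values are computed in
double precision and stored as float32 for integer-count inputs (exact for
camera counts; rounding to nearest cannot carry a convex combination past
either endpoint). Re-enhancing an enhanced stack is refused rather than
silently applied. The remaining 0.06 vs 0.05 µm in-plane/axial mismatch is
accepted; no X/Y resampling, deconvolution or denoising is performed.

## Nucleus segmentation

Segmentation is 2D and slide-by-slide — a nucleus spans 10–20 real slides
but ~1500 px in-plane, so per-slide detection is more robust than direct
3D segmentation even after enhancement. Per slide: DAPI counts strictly
above 500 are ON; 8-connected components are ranked by area and the top
15 kept; each is refined by hole filling, 10 binary dilations with the
full 3×3 element, and a second hole filling; the refined region is
accepted if its area is at least 100 000 px **and** its circularity
4πA/P² strictly exceeds 0.4. The circularity stands in for a per-slide
"sphericity": the 3D sphericity formula is dimensionally meaningless for
a 2D section, and 4πA/P² is its natural planar analogue (disk = 1).
The perimeter P is the weighted boundary-step count of the traced contour
(diagonal steps √2), which keeps digitized disks near 1.

The area gate scales with image area: 100 000 px corresponds to a nucleus
in a 1500×1500 field, and analyses of smaller synthetic fields use a
proportionally smaller `min_nucleus_px` (5 000 at 256×256).

Boundaries come from Sobel gradients in X and Y on the binary mask,
combined as the magnitude and binarized at > 0. The image is padded with
zeros (background) outside the frame so that frame-touching nuclei still
yield closed boundaries; for a region not touching the frame the result
is a thin ring straddling the region edge, and restricted to region
pixels it equals the set of true pixels with at least one false
8-neighbour. Accepted per-slide regions are stacked along z and joined
into 3D nuclei by 26-connected labeling (regions overlapping in
consecutive slides share a nucleus). Because the 10-step dilation is part
of the published refinement, the final mask extends ~10 px (0.6 µm)
beyond the DAPI boundary; the offset is common to all conditions and
cancels in comparative statistics.

## Channel alignment

The ER channel shows a small systematic in-plane offset against H3K27ac.
For each evaluated slide the integer shift maximizing the Pearson
correlation of the overlapping pixels is found by exhaustive search in
[−max_shift, max_shift]² (default 50 px; 25 % minimum overlap enforced).
Ties within 1e−12 resolve toward the smallest |dy|+|dx|, then
lexicographically. Because the offset is systematic, the default applies
one global correction — the median of per-slide estimates over the
brightest slides (default 5) — with a per-slide mode available. Only
integer translations are applied: vacated pixels are zero-filled and
masked invalid so they never enter correlation features. No rotation,
scaling or Z correction is modelled.

## Domain detection

The intensity threshold is data-driven: all voxels outside every detected
nucleus form the background sample, and the threshold is its 99.9th
percentile (top 0.1 percentile), linear-interpolation convention (the
convention is recorded in the output because boundary cases differ
between conventions). In-nucleus voxels strictly above threshold are
joined into 3D components with the full 26-neighbourhood — the 3D
analogue of the 2D 8-connectivity used elsewhere — and refined *per
component* (hole filling, 2 dilations with the 3×3×3 cube, hole filling),
so dilation can never merge two nearby domains.

Size filtering keeps domains in the 10–100 000 voxel range (inclusive).
The lower bound is applied to the pre-refinement seed component: two cube
dilations inflate even a single hot voxel to ≥ 25 voxels, so only the
seed size can discriminate isolated noise voxels (which the threshold
definition guarantees at a ~0.1 % voxel rate) from real domains. The
upper bound is applied to the refined voxel set the domain keeps, so
every retained domain satisfies 10 ≤ |voxels| ≤ 100 000. A consequence of
the fixed 2-step dilation is a systematic ~2-voxel fattening of every
domain: overlap with ground truth (Jaccard) only exceeds 0.5 for domains
of radius ≳ 12 voxels, although detection *counts* are accurate down to
much smaller sizes.

## Per-domain features

* **H3K27ac–ER correlation**: sample Pearson r over the domain's voxels,
  using the aligned ER channel and skipping alignment-invalidated voxels;
  zero-variance or under-sized vectors are recorded as missing with a
  reason.
* **Volume**: the voxel count, also converted to µm³ with the enhanced
  voxel volume (0.05 × 0.06 × 0.06 µm³). Both are reported.
* **Sphericity**: φ = π^(1/3)·(6V)^(2/3)/S with V from the voxel count
  and S the area of the level-0.5 marching-cubes isosurface in physical
  units. Meshing the raw 0/1 occupancy grid leaves a faceted staircase
  surface about 9 % larger than the smooth body it digitizes (a
  radius-10 ball would score ~0.91), so the grid is Gaussian-smoothed
  (σ = 0.8 voxels) before meshing; the digitized ball then scores 1.009
  and a 4:1 prolate spheroid matches its closed-form area to < 1 %.
  Counting exposed voxel faces instead (kept only as a fallback for
  degenerate meshes) would overestimate S by ~50 % and cap φ(ball) near
  0.67. Because V stays the voxel count, bodies only ~3 voxels in radius
  can score slightly above 1; φ is used comparatively, where the bias is
  common to all conditions.
* **Boundary distance**: Euclidean distance in µm from the domain's
  unweighted voxel centroid (one distance per domain) to the nearest
  nuclear boundary voxel, via a KD-tree in physical coordinates. Since
  nuclear boundaries are extracted per slide (in-plane), axial "cap"
  surfaces are not represented; with a nuclear Z-extent of ~1.5 µm
  against ~10 µm in-plane, the nearest boundary is essentially always
  lateral.
* **Volume class**: four ordered classes split at the pooled 25/50/75th
  volume percentiles across all conditions (pooled, so per-condition
  class proportions are free to differ — the quantity of interest);
  explicit fixed thresholds are accepted as an alternative.
* **Gini index** (per cell, per feature): G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄),
  computed by the sorted-form identity; 0 for identical domains, rising
  with heterogeneity, scale-invariant. The plain n² denominator is used
  (no small-sample bias correction). It is computed for the non-negative
  features (volume, sphericity, boundary distance), not for the signed
  correlation.

## Group statistics

Stack-derived features are compared with one-sided two-sample t-tests.
Welch's unequal-variance form is the default (the pooled form is a flag):
with per-condition variances unknown and often unequal, Welch is the
safer default. Per-batch summaries compute one t per (batch, comparison),
signed positive when the reference condition exceeds the other; batches
missing a condition are skipped with a log entry. Degenerate zero-variance
inputs resolve to t = 0, p = 0.5 at equal means and p ∈ {0, 1} otherwise.

Feature tables are screened for normality (Shapiro–Wilk plus a
Kolmogorov–Smirnov test against a normal with the sample's moments;
either p < 0.05 ⇒ non-normal; constant samples non-normal by convention)
and routed to a Kruskal–Wallis omnibus test; only if the omnibus p < 0.05
do pairwise two-sided Mann–Whitney U tests run, their p-values multiplied
by the number of pairs actually tested within that analysis (Bonferroni,
capped at 1) — the correction scopes to one feature/analysis, matching
per-figure annotation practice, not across features. Significance stars
default to \* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001; a stricter map
(\* p < 0.01, \*\* p < 0.001, \*\*\* p < 0.0001) used by some figure
conventions ships as `STRICT_STAR_MAP`, and the map is configurable.

## Synthetic-data generator

The generator emulates the statistical structure of the experimental
conditions on the acquisition grid, not the optics: there is no PSF,
photoswitching, or SIM reconstruction artifact model, and domains are
rendered as clean geometric solids plus rounded Gaussian camera noise
clipped at zero. Passing tests therefore demonstrate correctness of the
measurement pipeline on well-posed inputs, not robustness to
reconstruction artifacts, uneven staining or touching nuclei.

Per stack: an ellipsoidal nucleus (default semi-axes ~0.33/0.42/0.37 of
the grid with a small seeded jitter) renders DAPI at 2000 ± 150 counts
inside and 100 ± 50 outside, far on either side of the 500-count
segmentation cutoff. Chromatin domains are balls or spherocylinders
(capsules) defined in physical micrometres — so the anisotropic voxel
grid yields correct 3D shapes — with radius `domain_radius_vox` × 0.06 µm
and capsule half-length r·(elongation − 1), axis uniform on the sphere.
Domain count is Poisson; placement samples a radial position in ellipsoid
coordinates (uniform-in-volume, or pulled into a 0.78–0.92 shell with
probability `boundary_bias`), requires the whole body inside the nucleus
(checked cheaply via end-balls against the radius-shrunk ellipsoid, exact
by convexity), and rejects candidates within 1 in-plane voxel / 2 axial
slides of an existing domain — domains are distinct bodies, and without
that margin Z-interpolation can bridge single-slide gaps and make the
ground-truth count ill-defined.

H3K27ac renders each domain at a per-domain level ~N(intensity_mean,
intensity_sd) plus per-voxel noise of the same sd; background is
N(120, 40) outside the nucleus and N(120, 25) in the nucleoplasm — SIM
reconstructions are noisiest outside the specimen, and the tighter
nucleoplasmic spread keeps the background-derived threshold meaningful
inside the nucleus. The ER channel mixes the standardized in-domain
H3K27ac signal with independent noise, ER = ρ·H̃ + √(1−ρ²)·ε scaled to
its own mean and sd, so the target Pearson correlation holds in
expectation; ρ = ±1 degenerates to an exact (integer-preserving) affine
map. The ER channel is then rigidly shifted by the configured integer
(dy, dx) with zero fill. Cohorts derive per-cell seeds from the master
seed via `SeedSequence(master, spawn_key=(batch, cell-index))`, so any
single cell is reproducible in isolation; optional per-batch intensity
offsets emulate staining batch effects.

Condition presets (the defaults used by the acceptance computations):

| parameter | ED-like | E2-like |
|---|---|---|
| shape | sphere | capsule, elongation 4 |
| radius | 3 xy-voxels (0.18 µm) | 3 xy-voxels |
| domains/cell (mean) | 25 | 25 |
| intensity mean ± sd | 1500 ± 250 | 1800 ± 250 |
| ER correlation ρ | 0.3 | 0.6 |
| boundary bias | 0.7 | 0.0 |
| ER shift (dy, dx) | (3, −2) | (3, −2) |

The problem sizes used throughout the tests and the
acceptance script are 256×256 px × 10 real slides per cell and cohorts of
2 conditions × 10 cells × 2 batches; the nucleus size gate is scaled to
5 000 px accordingly and the shift search window to cover the preset
offset. These sizes keep a full 20-seed end-to-end evaluation within a
few minutes while preserving every qualitative property of the
full-field geometry.

## Known limitations

* Touching or overlapping nuclei are not split (no watershed); the
  generator produces one nucleus per field.
* Boundary distances inherit the ~0.6 µm outward offset of the dilated
  nucleus mask and ignore axial cap surfaces (both common-mode across
  conditions).
* Sphericity of very small domains (< ~5 voxels radius) is biased
  upward by the voxel-count volume convention.
* The t type-I calibration and directional-recovery rates are exact
  properties of the synthetic conditions; real data adds sources of
  variation (staining, reconstruction artifacts) the generator does not
  model.
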