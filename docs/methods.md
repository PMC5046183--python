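# Methods

## Pipeline

Given an RGB tile, detection proceeds: channel selection → Gaussian
smoothing → Canny edges → unit inverse-gradient field masked to the edge
set → edge-fragment extraction and validity labelling → gradient
refinement (none / GS1 / GS2) → multi-pass fan voting → Otsu threshold on
the normalised vote image → connected-component centroids as seeds.

Coordinates are 0-based with x = column, y = row; angles are measured from
the +x axis counter-clockwise in image coordinates (y down). All module
tunables live in `RunConfig` (flat `key = value` text files; unknown keys
rejected), and each CLI run writes its resolved configuration next to its
outputs.

## Channel selection

The detector votes on a single scalar raster in which nuclei are darker
than background. The default is the raw red channel (hematoxylin-family
stains absorb strongly there, and it needs no estimation step). Rec.601
luminance is available, as is sparse-NMF colour deconvolution in optical
density (`od = −log10(max(I,1)/background)`): the OD matrix is factorised
as `OD ≈ W·H` with an L1 penalty on the concentrations H (weight 0.1,
coordinate-descent solver, deterministic NNDSVD-based initialisation,
200 iterations), stain vectors normalised to unit columns and ordered by
descending blue-channel OD so a hematoxylin-like stain comes first.
Sparse-NMF deconvolution is only identifiable when stain co-expression is
sparse (most pixels dominated by one stain) — true of real tissue, and of
the synthetic mixtures used in tests; on dense mixtures the factorisation
is not unique and recovered vectors can be arbitrarily rotated. A
`channel.invert` flag handles preparations where nuclei are bright (e.g.
a concentration raster, or DAB-dominant channels). Stain normalisation
across slides is out of scope.

## Gradient field

Smoothing uses a reflective-boundary Gaussian with σ_Gau = 1.5 px
(appropriate for 15–40 px nuclei at ~0.25 µm/px; configurable). Gradients
are central differences on the smoothed image; the inverse gradient is
negated and normalised to unit length where the raw magnitude exceeds
1e-12 (voting uses direction only). Canny hysteresis thresholds are
expressed as fractions of the maximum Sobel gradient magnitude
(low 0.1 / high 0.3 by default), making them invariant to intensity
scale. The field is zeroed off the edge set.

## Refinement

Edge fragments are 8-connected components (Canny emits diagonal chains),
ordered by their top-left-most pixel. The reference point `C_i` is the
area centroid of the *filled* convex hull (shoelace formula on the hull
polygon), robust to uneven pixel density along the contour; fragments with
fewer than three non-collinear pixels fall back to the mean coordinate.
θ is the angle between the unit inverse gradient and the pixel→`C_i`
bearing, clamped to [0, π]; a pixel coinciding with `C_i` gets θ = 0.
Pixels are valid iff θ ≤ π/2 (+1e-12 for float safety): a gradient
pointing toward the hull centroid contributes constructively to the
symmetry vote. The exactly perpendicular case is kept valid — it neither
helps nor hurts, and inclusion preserves the support-equality invariant of
GS2. GS1 zeroes invalid vectors, GS2 negates them, `none` leaves the field
untouched; valid pixels always keep their original vector, so refinement
is a no-op on contours of solid convex objects.

## Voting

An active pixel p with direction α votes into the fan
`A(p; r_min, r_max, α, δ)` (δ is the *half*-aperture; full fan angle 2δ).
Defaults follow the documented operating point: r_min = 1, r_max = 40 px,
kernel σ = 4 px, N = 3 passes, δ_max = π/4 with geometric halving
(δ_i = δ_max/2^(i−1)); an explicit schedule can be supplied and must be
strictly decreasing.

The kernel is an **oriented** Gaussian centred at the radial midpoint
(r_min+r_max)/2 along α and truncated to the fan: cross-axis std σ = 4,
along-axis std σ_r = (r_max − r_min)/4 so the vote mass covers the whole
radial range. The choice is deliberate. With an isotropic kernel at the
midpoint, a disk of radius r accumulates pass-1 votes on a *ring* of
radius |20.5 − r| around its centre (for r outside ≈ 16–25 px the
overshoot exceeds σ), and the argmax direction update then condenses that
ring into off-centre spots — systematic localisation errors of 5–13 px on
10–16 px nuclei. With the oriented kernel every boundary pixel's kernel
axis passes through the centre of a convex object, so the pass-1 votes of
the whole contour are *concurrent* at the centre and the vote image peaks
there for any radius inside [r_min, r_max].

Passes are not cumulative: each `V_i` accumulates from zero. Between
passes every active pixel re-aims at the maximum-vote pixel inside its
current fan (ties broken by distance to the voter, then row-major order;
a fan with no raster pixels leaves the direction unchanged). The chosen
target also becomes the pixel's kernel centre for the next pass, and the
along-axis σ_r halves per pass (floored at σ): the first pass must spread
votes over the radial range because no vote information exists yet, while
refined passes deposit compact mass on their targets. Without this
re-centring, the long axis of a fixed midpoint kernel bridges the peaks of
nuclei ~30 px apart into a single above-threshold component. `V_N` is
divided by its maximum (all-zero maps stay zero) so the detection
threshold lives on [0, 1].

## Seeds

`T_D` is Otsu's threshold computed on a fixed 256-bin histogram over
[0, 1] (not the data range), so thresholds are comparable across images
and with the PR-sweep grid; the returned value is the upper edge of the
background class, and binarisation is strict (`V_N > T_D`), making
`T_D = 1` yield zero detections. A constant image returns that constant.
Detections are 8-connected component centroids, scored by the component's
mean vote, ordered row-major by component origin; `seeds.min_area`
(default 1: no filtering) can drop small components.

## Evaluation

Matching is greedy nearest-first one-to-one within 15 px: candidate pairs
sorted by distance (ties by detection then ground-truth index), accepted
while both endpoints are free. One-to-one-ness prevents a single detection
from claiming several nuclei; at realistic tile densities (50 nuclei per
500×500 px) greedy TP counts sit within ±1 of the optimal assignment on
≥95% of random configurations (verified against a Hungarian-algorithm
oracle in the tests). The PR curve pools TP/FP/GT over all images of a
cohort at each threshold of the 21-point grid; AUC is the trapezoid over
observed recall values with no extrapolation. At a threshold with zero
pooled detections the curve uses the empty-detection limit precision = 1
(the single-report `rates` function keeps the P = 0 convention for
`n_det` = 0); with P = 0 there, a perfect detector's curve would
integrate to 0.5 rather than 1, contradicting the quantity's purpose.
Per-image AUCs feed a two-sample t-test between methods (Student's
equal-variance by default, Welch by flag; identical constant groups give
p = 1 by convention; significance at 0.05).

## Phantoms

Generators rasterise at 4× supersampling (anti-aliased rims give clean
single-pixel Canny contours; hard edges produce double contours that
confound fragment counting), then add Gaussian noise (σ = 3 by default)
and replicate to RGB. Default intensities: background 220, nucleus 90,
hollow core 200 — a pale core bright enough to produce an inner contour
with outward inverse gradients. All generators are deterministic given the
seed, and ground-truth centres are returned alongside the image.

* **Solid disks** — convex nuclei; the all-valid control. The random
  placer keeps centre distances ≥ r_i + r_j + gap (gap 5 px by default).
* **Hollow nuclei** — annuli (ring thickness < radius); each yields an
  outer contour (valid, inward gradients) and an inner contour (≥95%
  invalid, outward gradients).
* **Hollow cluster** — the false-positive trap. Three annuli (outer
  radius 15, ring 4.5) on a 31 px circumcircle, with *poorly stained*
  intensities: background 210, ring 200, core 255. The outer boundary's
  contrast (10) sits below the Canny hysteresis cut relative to the inner
  contour's (55), so only the three inner contours survive — the
  "ill-defined nuclear contour with a hollow interior" regime. Quantitative
  counting shows why the faint outer boundary is necessary and not merely
  convenient: with full contours the void can collect at most ~25% of a
  contour's concurrent vote mass (the alignment cone σ/R limits
  void-aligned inner voters to ~3–5 per nucleus against ~90 concurrent
  outer-contour voters), which always falls below the Otsu threshold —
  for any kernel shape. With the outer boundary gone, unrefined voting
  has only outward gradients: their scatter rings (radius r_in + 20.5
  around each nucleus) all pass through the central void, which sits at
  the kernel-centre distance 20.5 px from each inner contour
  (circumradius 31 = 20.5 + inner radius 10.5), making the void the
  global vote maximum. Result: plain multi-pass voting detects the void
  and its ring intersections (several false positives, no true centres);
  GS2 reverses the gradients and recovers exactly the three centres; GS1
  suppresses every vote and detects nothing — a clean illustration that
  reversal, not suppression, is the stronger strategy when contours are
  mostly invalid.

What the phantoms do **not** emulate: texture (chromatin, stroma),
touching/overlapping nuclei, elliptical or irregular shapes, stain
variation across a slide, and uneven illumination. Passing the phantom
suite therefore demonstrates the correctness of the voting/refinement
machinery and the evaluation harness under the stated geometric regimes —
not detection performance on real tissue.

## Benchmark bookkeeping

`evaluate.BENCHMARK_COHORTS` records the published four-cohort benchmark
this evaluation protocol was designed around (breast H&E, breast
CD31 & hematoxylin, skin Ki-67, breast H&E; 0.2455–0.2514 µm/px; 4598,
5248, 1998 and 5859 labelled nuclei). The image data are not
redistributed; the table supports unit conversions (15 px ≈ 3.6825 µm in
cohort A) and totals (11 844 nuclei across the first three cohorts).

## Numerical choices and degenerate inputs

Angles wrap to (−π, π]. Vote accumulation is order-independent (pure
summation; permutation changes results only at ~1e-13). An empty gradient
support yields an all-zero vote image, threshold 0, and no seeds. Hull
computation falls back to the coordinate mean on collinear fragments.
`rates` refuses n_gt = 0 (recall undefined). The brute-force voting
oracle, exhaustive Otsu search, and Hungarian matcher used in tests are
independent re-implementations, not calls into the package.

## Problem sizes

The test suite and the acceptance script run phantoms of 96–256 px on a
side with 1–10 nuclei (≈ 200–1200 active edge pixels), three voting
passes each; the standard benchmark suite is three images with 19 nuclei
total. These sizes make every regime measurable while keeping a full run
in seconds on one CPU.

## Known limitations

* Nuclei larger than ~r_max/2 or images at very different resolutions
  need rescaled voting parameters; defaults assume ~0.25 µm/px.
* A single edge fragment spanning several touching nuclei gets one hull
  centroid, which can mislabel pixels; fragment splitting is out of scope.
* Greedy matching can differ from the optimal assignment in crowded
  fields (documented gap ≤1 TP at tile density, larger when detections
  are much denser than nuclei).
* Watershed/level-set segmentation downstream of the seeds, and
  mean-shift clustering of single-pass vote maps, are deliberately not
  implemented.
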