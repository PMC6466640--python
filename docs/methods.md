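# Methods

This note records the model, the numerical choices, and the boundaries of
what the synthetic validation can and cannot show. It is the maintainer's
account of *why* the code is the way it is; the README describes *what* it
does.

## Coordinate and grid conventions

Arrays are ordered `(slice, row, col)`, 0-based. Rows increase posteriorly
(the spine sits at high row index), columns toward patient left, slices
inferior→superior. World coordinates are millimetres with, by default, the
volume centred on the origin; `Geometry.origin_mm` pins voxel `(0,0,0)`
when two grids of different extent must be aligned. The two grids are the
planning kVCT (1.953 mm pixels, 3 mm slices, 272×272) and the daily MVCT
(0.754 mm pixels, 6 mm slices, 512×512, 8–12 slices).

The setup-correction transform maps daily-grid world coordinates to
planning-grid world coordinates (in-plane translation + roll about the
cranio-caudal axis, |roll| < 15°). Structures are propagated by
transforming their marching-squares boundary polygons and rasterising with
a pixel-centre-inside rule; images are resampled bilinearly in-plane with
nearest-slice matching through-plane (slice thicknesses differ 3 vs 6 mm,
and the clinical correction is in-plane).

## Intensity model

The HU→[0,1] transfer function is piecewise linear with breakpoints
(−130, −10, 30, 60, 100) HU: gas (< −130 HU) → 1, dead zone [−130, −10) → 0,
ramp up to 1 at 30 HU, plateau to 60 HU, ramp down to 0 at 100 HU, 0 above.
The −130 HU gas threshold is deliberately far above −1000 HU: real rectal
gas pockets carry traces of solid matter and partial-volume voxels. Air
detection thresholds the *HU* image before rescaling — after rescaling,
gas and bright rectal content are indistinguishable by construction — and
is restricted to the search region, since the largest sub-threshold
component of any real slice is the air outside the patient.

## The active contour

The segmentation energy is the two-phase piecewise-constant model

E(Ω) = μ·Length(∂Ω) + ν·Area(Ω) + Σ_Ω (I−c₁)² + Σ_{ROI∖Ω} (I−c₂)²

with c₁, c₂ the region means (λ₁ = λ₂ = 1) and the background statistics
taken over ROI∖Ω only, because evolution never leaves the search region.
User-facing parameters map to internal weights as μ = smoothing × 0.05 × R²
and ν = bias × 0.3 → **0.1** × R², where R is the intensity peak-to-peak in
the ROI (1 for rescaled images). The ν scale was calibrated once on the
phantom suite: the criterion was qualitative — mild expansion of the eroded
seed that halts at the wall/background intensity step (whose squared-
difference data term is ≈ 0.16 under the phantom bands) — after which the
constant was frozen in the default configuration. With that scale the
tuned clinical values (smoothing 6, bias −1.0) reproduce the intended
behaviour, and final area is monotone in bias over {−0.9, −1.0, −1.1}.

**Evolution scheme.** A signed level set (positive inside) is advanced by
an explicit gradient step with a smeared delta (ε = 1 px) and the force
normalised to unit maximum. Each candidate region is regularised by a 3×3
majority filter — fronts advance as coherent rings rather than jagged
pixel sets — and accepted only if the *sharp-interface* energy (Crofton
perimeter estimate, exact pixel counts, optimal region means) does not
increase; otherwise the step size is halved (backtracking, floor 10⁻³).
After every accepted step the level set is reinitialised to a signed
distance; reinitialisation preserves the region exactly, so the logged
energy is unaffected and non-increasing *by construction*. Convergence is
declared when sign flips over a 10-iteration window fall below 0.1% of ROI
pixels; the cap is 300 iterations. The scheme is deterministic: identical
inputs give bit-identical masks. The output keeps the largest connected
component with holes filled — a rectal cross-section is one hole-free
region.

The seed is the propagated planning contour eroded once by a 3×3 element
(a prior too thin to survive erosion is used as-is), then placed by
exhaustive search over integer shifts in [−20, 20]² maximising summed
intensity under the mask, ties broken by smallest shift norm then
row-major order.

## Quality control and fallback

A slice is rejected if its contour touches the search-region border, or if
its area net of contained gas exceeds 2500 px (1420 mm²) outside the
muscle-associated region. The top of that region is the most superior
over-large slice among the bottom six, defaulting to the second-most
inferior slice; everything at or below it takes the planning contour.
Two exceptions, in order of precedence: a valid large daily gas region
supplies the contour directly, and planning-scan gas absent on the day
erodes the planning contour by the area difference (never to empty).
Medium gas (150–600 px) does not replace the contour; its hole-filled,
8 px-dilated region is merged into the seed and the pass-1 result — the
method never states how medium regions enter the contour, and merging is
the smallest-commitment reading consistent with "included within the
rectal contour".

## The smoothed surface and second pass

Each accepted contour becomes r(θ) on 100 angles about its own centroid
(outermost sub-pixel boundary crossing per angular bin; marching-squares
boundaries avoid the half-pixel ripple of pixel-centre boundaries). Across
slices this is a regular (θ, z) grid with z measured from the prostate
reference slice. The surface fit is:

* **θ**: least-squares projection onto Fourier harmonics 0–5 (periodic by
  construction; a single-angle spike retains ≈ 11/100 of its amplitude);
* **z**: per Fourier coefficient *and per centroid component*, a running
  median (window 3, mirrored ends) followed by a Huber-reweighted
  polynomial of degree ≤ 3.

Two choices here deserve their rationale. A generalised cross-validation
smoothing spline was tried first and degenerates to interpolation at these
sample sizes (8–12 slices): one displaced contour simply drags the surface
with it, and at an endpoint its leverage defeats plain robust reweighting
too — hence the median prefilter. Second, the centroids are smoothed for
*all* slices, not only excluded ones: the self-check compares each contour
to the surface rasterised at the *fitted* centroid, so a displaced but
well-shaped contour disagrees with the surface instead of being invisible
to it.

Slices with JCI < 0.5 against the surface are re-segmented seeding from
the eroded smoothed contour; the result is kept if it agrees with the
surface (JCI > 0.5), else the interpolated contour is used. Rejected
most-superior/most-inferior slices revert to the planning contour rather
than extrapolating. Fitted radii are floored at 0.5 mm (logged) — a
surface collapsing through zero would otherwise produce invalid polygons.

## Metrics

JCI and DSC are computed from the same pixel counts, so DSC = 2J/(1+J)
holds identically. Two empty masks score 1 (with a log message): a slice
correctly empty on both sides should not poison a mean; empty-vs-non-empty
scores 0. Cohort curves report mean ± SE (n−1 standard deviation) per
slice offset, dropping offsets contributed by fewer than five scans.

## The phantom: what it emulates, what it does not

The generator draws a per-patient anatomy (rectal tube with smoothly
varying centre and radius 11–15 mm, slightly elliptical; 3.5 mm wall at
38–55 HU; lumen at 0–25 HU; prostate ellipsoid at 40±10 HU abutting the
anterior wall; posterior spine and inferolateral ischial bone ≥ 700 HU;
soft-tissue background 0±20 HU filling the grid — no exterior air) and,
per daily scan: a rectal displacement ~N(0, 4 mm) per in-plane axis capped
at 12 mm, radius scaling U(0.9, 1.15), gas pockets in about a third of
scans (half of them large-tier, locally distending the rectum so the
pocket always fits the lumen), a transient bowel loop isointense with the
wall lateral to the rectum in 40% of scans, contrast compression
HU′ = 0.7·(HU−20)+20 on soft tissue, additive N(0, 25 HU) noise, and a
couch error (≤ 8 mm shift, ≤ 3° roll) whose inverse is the returned setup
correction. The inferior slices (below z = −18 mm) carry a muscle band at
35–55 HU directly abutting the wall, so the active contour over-segments
there exactly as the fallback logic expects. The displacement scale is a
typical interfraction rectal motion, chosen once; the noise/contrast
values are the study conditions of the benchmark.

Deliberately absent: beam hardening, scatter, ring artefacts, partial-
volume mixing at boundaries, non-circular (collapsed/crescent) rectal
cross-sections, and observer variability in the "manual" planning
contours, which are analytically exact. Passing the phantom benchmark
therefore demonstrates the mechanics of the pipeline — priors, QC routes,
3D self-check, every provenance path — under controlled degradation, not
clinical-grade accuracy on real anatomy. Conversely the phantom's exact
ground truth makes the benchmark stricter than an inter-observer
comparison in one respect: there is no delineation noise to hide behind.

One phantom-vs-clinic interaction worth knowing: when the day's
deformation happens to be small, the propagated planning contour is a
near-perfect baseline on that scan and can outscore the active contour
slice-by-slice; the pipeline's advantage appears in the cohort mean, where
large deformations dominate the baseline's error.

## Problem sizes and runtime

Default study: 10 patients × 3 daily scans (≈ 300 slices), the scale of
the clinical validation set it mirrors. A full cohort run — generation,
segmentation, scoring — takes ≈ 90 s on one CPU; the test suite ≈ 2 min.

## Known limitations

* The 2D-per-slice contour has no through-plane coupling during evolution;
  3D consistency is imposed only afterwards by the surface check.
* The muscle-region rule is index-based (bottom six slices); a very
  superior field of view would mislabel it.
* The air-modified planning fallback (erode by the gas-area difference) is
  crude and is the weakest route in per-provenance accuracy — consistent
  with its known behaviour — but it is rare (≈ 1% of slices).
* Polar profiles use the outermost boundary crossing, which over-covers
  strongly non-star-shaped contours (logged when the centroid falls
  outside the mask).
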