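# Methods

This note documents the measurement model, the numerical choices, the
synthetic phantom that stands in for clinical data, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

All measurements are taken on segmentation masks; where the masks come
from is outside the library's concern (the backend contract is two
functions: `segment_frame` returning labeled instances with
confidences, and `classify_criteria` returning per-criterion
probabilities for head and abdomen planes). All internal lengths are
centimetres. DICOM `PixelSpacing` is row-then-column in millimetres and
is converted to cm exactly once at ingest; this single-unit discipline
is what prevents the classic 10× error.

**Head and abdomen.** The outer contour of the largest 8-connected
component is traced sub-pixel at the 0.5 iso-level (marching squares).
The contour is fitted with the direct least-squares ellipse fit: the
algebraic conic fit constrained to `4ac − b² = 1`, solved in the
numerically stable partitioned (3+3) eigen-formulation. Input points
are centered and scaled to unit RMS radius first; without this
preconditioning the single 6×6 eigenproblem is badly conditioned for
near-circular skulls, which are the common case. The perimeter (HC, AC)
is the exact elliptic-integral form `4a·E(m)`, `m = 1 − (b/a)²`,
evaluated with `scipy.special.ellipe`; the circle limit `2πr` and the
degenerate limit `4a` at `b = 0` are exact, and the test suite checks
the value against independent adaptive quadrature of
`4a∫₀^{π/2}√(1 − e²sin²t)dt` at 1e-10 relative. BPD is the full
minor-axis diameter `2b` (outer-to-outer; no outer-to-inner skull-table
correction), so HC and BPD always come from the same mask.

**Femur.** FL is the long side of the minimum-area rotated rectangle of
the occupied pixels (computed on the convex hull; rotating calipers via
shapely). An axis-aligned box would understate the length of an angled
femur, and angles up to 45° are admissible. Caliper endpoints are the
midpoints of the rectangle's short sides. When the rectangle is exactly
square the axis closer to horizontal is chosen — a determinism rule for
a measure-zero case. Note that for non-convex shapes the minimum-area
box is a property of the hull, not of any single elongated part; this
is the defined measurement.

**Pixel-extent convention.** Lengths are measured between outermost
pixel *centers* (`max − min`), matching where caliper tips are placed;
a 61-pixel-wide bar therefore measures 60 px.

**Amniotic fluid.** There is no plane-quality selection for the fluid
sweep: every pocket instance on every frame is measured and the deepest
retained (this mirrors how a sonographer sweeps all pockets and keeps
the deepest). Depth is the vertical extent of the pocket's axis-aligned
bounding box, converted with the *row* spacing; a rotated pocket's true
vertical chord may differ, but the bounding-box rule is the defined
measurement. Categories use strict inequalities: oligohydramnios
< 2 cm, polyhydramnios > 8 cm, normal otherwise.

**Anisotropic spacing.** Ellipse perimeters and rotated axes mix row
and column directions, so their conversion demands isotropic spacing
(tolerance 1e-6 cm); the package raises rather than averaging, because
an averaged spacing silently corrupts the measurement.

## Quality scoring and frame selection

Each candidate instance is scored
`composite = (w_q·Q + w_z·Z + w_c·C) / (w_q + w_z + w_c)`:

* `Q` — mean of the plane's criterion probabilities. Abdomen: kidneys
  not visible (A_KN), portal sinus (A_PS), stomach bubble (A_SB),
  symmetry (A_SYM). Head: cerebellum not visible (B_CB), cavum septum
  pellucidi (B_CS), posterior ventricle horn (B_PVV), symmetry (B_SYM),
  thalami (B_TH). The femoral plane has no criterion classifier (the
  "both ends visible" criterion is notoriously unreliable to learn);
  its Q is the indicator that the femur lies within 45° of horizontal
  (strict inequality), derived from the mask itself.
* `Z` — zoom conformity: the structure's area fraction reaches the
  plane threshold. Head and abdomen use 0.5 ("occupying more than half
  of total image") literally. A thin femur cannot cover half the *area*
  of any frame, so its default threshold is 0.05 — the fraction a
  well-zoomed femur spanning about half the image width actually
  covers. All thresholds are configurable per structure, and a raw-ratio
  mode (Z = area fraction instead of the indicator) is available.
* `C` — the backend's detection confidence, an opaque scalar in [0, 1];
  confidences from different backends are not comparable.

Weights default to equal thirds; nothing in the criterion definitions
fixes them, so they are configuration. The highest composite wins,
earliest frame on ties. "Calipers placed correctly" criteria are
outcomes of this pipeline's own deterministic caliper computation and
are recorded as always conformant. An empty candidate list yields a
reportable *no-plane-found* outcome, not an exception: partially
complete examinations are normal clinical reality.

## Clinical formulas

Coefficients live in `FormulaConfig` and are overridable without code
changes.

* Hadlock (3-parameter), lengths in cm, EFW in grams:
  `log10 EFW = 1.335 − 0.0034·AC·FL + 0.0316·BPD + 0.0457·AC + 0.1623·FL`.
  EFW requires exactly AC, FL and BPD; there are no fallback formulas.
* Intergrowth (> 14 weeks), GA in days:
  `ln GA = 0.03243·(ln HC)² + 0.001644·FL·ln HC + 3.1813`, inputs in mm
  by default (the convention of the formula's source; configurable and
  recorded in report provenance).

**Known discrepancy.** With the intercept 3.1813 as printed, mm-scale
inputs give implausibly low GA (HC 250 mm, FL 50 mm → ≈ 102 days,
i.e. ~14.5 weeks for late-second-trimester biometry). The originally
published Intergrowth coefficient set differs; this package
deliberately implements the printed value as the default rather than
silently "fixing" it, and exposes `k_0` in configuration. Downstream
users comparing GA against clinical expectations should override the
intercept with the value from the primary Intergrowth publication.

Weeks+days rendering is `floor(GA/7)` weeks plus the rounded remainder,
with a carry when the remainder rounds to 7.

FGR percentile classification is out of scope: it requires external
growth-standard tables, and only a hook accepting a user-supplied
percentile table would be meaningful. The four-quadrant AFI method and
first-trimester CRL dating are likewise not implemented.

## Agreement statistics

* Bland-Altman: differences `a − b`, bias = mean, limits
  `bias ± 1.96·sd` with sample sd (n−1). Percentage mode divides each
  difference by the pair mean `(a+b)/2` (the standard percentage form;
  pairs with zero mean are a domain error listing the offending
  subjects). 1.96 is a constant, not a configurable quantile.
* ICC: for two raters on balanced data the one-way random-effects
  ICC(1,1) reduces to `(MSB − MSW)/(MSB + MSW)`, implemented directly
  from the ANOVA mean squares (it may be negative). A two-way
  absolute-agreement single-measure variant, ICC(2,1), is available via
  `icc(series, model="two-way")`.
* Paired Wilcoxon signed-rank, two-sided. Zero differences are dropped
  (Wilcoxon's original procedure); ties in |d| receive mid-ranks. For
  n ≤ 25 the null distribution of W⁺ is exact, computed by convolution
  over the doubled mid-ranks (integers); above that a normal
  approximation with tie correction and continuity correction is used.
  The naming in the clinical literature sometimes says "rank sum" for
  paired data; what is meaningful (and implemented) for paired
  measurements is the signed-rank test.
* Dice and IoU are both defined as 1.0 when both masks are empty
  (agreement on absence), so per-image averages are well defined.

## The phantom: what it emulates and what it does not

The phantom generates cine-loops with *exact* planted truth: an
elliptical head/abdomen cross-section or a rotated femur capsule
(cap-tip to cap-tip length) whose scale follows a Gaussian peak across
frames (floor 0.6, width 0.6 frames) centred on a planted best-frame
index — a sweep dwells on the optimal plane only briefly — and, for the
amniotic sweep, disjoint pockets whose rasterized vertical extents
equal the requested depths snapped to the pixel grid. Criterion flags
and confidences are planted *metadata*, not rendered anatomy: the
pipeline consumes classifier probabilities, so testing selection logic
needs controllable flags, not realistic thalami. Only the best frame
has all flags true, conforming zoom, and maximal confidence (0.95
vs. 0.55–0.85 elsewhere); the generator enforces zoom uniqueness at
construction and rejects specs that violate it.

Default study conditions, chosen once to match a third-trimester
examination: 256×256 frames, 11 frames per sweep, 0.05 cm/px spacing
(0.03 cm/px femoral), head/abdomen semi-axes ≈ 120×90 px (HC/AC
≈ 33 cm, BPD ≈ 9 cm), femur 185 px ≈ 5.5 cm, pockets 2–7 cm. The
validation study samples geometry within bands derived so that the zoom
rule stays discriminative under mask degradation: erosion by 2 px may
not drop the best frame's area below its threshold, and dilation by
2 px may not lift a neighbour above it (for the ellipse this pins
πab between about 0.525 and 0.58 of the image area).

The oracle backend returns the planted masks, optionally degraded by
morphological erosion or dilation of radius drawn in {0..k} (sign and
radius per frame, seeded) plus optional boundary-pixel jitter. This
emulates the boundary error of a real segmenter while keeping truth
exact. Speckle is multiplicative unit-mean gamma noise (shape 16 by
default) — enough to exercise intensity-agnostic code paths.

**Not emulated:** attenuation, shadowing, refraction, reverberation,
probe geometry, fetal motion between frames, twins, or any wave
physics. Passing the phantom study therefore demonstrates that the
*measurement and selection machinery* is correct given masks of
bounded boundary error; it says nothing about the difficulty of
producing such masks from real ultrasound, which is the segmentation
backend's problem.

## Annotation extraction

Burned-in overlays are detected by palette matching (default saturated
yellow/green/cyan/magenta, per-channel tolerance ±40 — vendor palettes
vary and these are configurable guesses validated on synthetic
renders). Connected components are gated by normalized correlation
against cross/x glyph templates (threshold 0.6), which rejects
palette-colored rectangles and text fragments; marks are taken at
component centroids. Dotted-ellipse reconstruction feeds dot-cluster
centroids to the direct least-squares fit with one reject-and-refit
round; the rejection cut adapts to the residual scale
(max(2 px, 3×median)) because a gross outlier distorts the first fit
enough to inflate all residuals. OCR itself is an external interface —
only its text lines are parsed (decimal comma tolerated, `AF`
normalized to `SDP`, unknown acronyms skipped with a warning). Femur
annotations are polygon masks ingested directly; there is no overlay
reconstruction path for them.

## Numerical and policy choices

* Degenerate inputs raise typed errors: empty masks
  (`EmptyStructureError`), under-determined or non-elliptical fits
  (`DegenerateFitError`), sub-8-point boundaries. A candidate frame
  whose best instance cannot be measured is skipped in favour of the
  next-best candidate before declaring no-plane-found.
* Reports serialize to canonical JSON (sorted keys, fixed layout);
  NaN/infinity are schema violations. Identical inputs, seeds and
  configuration produce byte-identical phantoms and reports.
* Every stochastic element (phantom sampling, degradation, speckle)
  is driven by explicit seeds; the pipeline itself is deterministic.
* The validation study sizes (200 phantom cases, 100 annotation
  frames, ICC at n = 500) keep the full run in tens of seconds on one
  CPU while leaving the acceptance margins interpretable.

## Limitations

* Video-container ingestion requires an imageio decoding plugin; DICOM
  and frame-directory ingestion are the first-class paths.
* Only uncompressed and common JPEG-baseline DICOM transfer syntaxes
  are supported.
* The composite score's functional form (weighted sum) and its default
  equal weights are design choices; nothing in the criterion
  definitions fixes them, and a lexicographic or learned combination
  would be a reasonable alternative behind the same interface.
* SDP's bounding-box depth overestimates oblique pockets; HC/BPD assume
  the skull outline is well approximated by an ellipse.
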