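# Methods

This note documents the models, parameter choices and numerical
conventions behind `sonoquant`, and what the synthetic validation does
and does not demonstrate.

## Coordinate and intensity conventions

All pixel coordinates are (row, col), 0-based, with half-open boxes
[top, bottom) × [left, right); rows increase with depth. Intensities
are bytes 0–255 at the I/O boundary, floats in [0, 1] inside the
filtering stage. Brighter always means stronger echo: DICOM
MONOCHROME1 input is inverted at read time so thresholds behave
identically across formats. Physical calibration comes from DICOM
`PixelSpacing` (millimetres per pixel, converted to cm) when present,
else from the config key `cm_per_px`; uncalibrated images are measured
in px/px² and flagged via the `units` column rather than rejected.

## ROI extraction

The informative region is found by a center-out threshold scan: from
the middle column outward, the outermost columns (left and right) whose
maximum intensity inside a vertical band exceeds a threshold; then,
restricted to those columns, the outermost supra-threshold rows above
and below the middle row. Defaults: threshold 10/255 (the frame around
the echo field is near-black, not exactly black), vertical band
25–75% of image height (avoids device overlays near the top/bottom
edges), minimum ROI area 64 px. A column/row counts as supra-threshold
when its *maximum* exceeds the threshold — a single bright speckle is
enough, which is deliberate: the scan's job is to find the transducer
field, not to denoise. A direction with no supra-threshold pixel
raises an empty-ROI error, treated downstream as a failed capture.

Filtering runs strictly *after* ROI detection so smoothing cannot blur
the field edge the scan keys on; an integration test asserts the scan
sees raw intensities.

## Bilateral filter

Standard bilateral weighting on [0, 1] intensities: each output pixel
is the Gaussian(spatial) × Gaussian(intensity) weighted mean of its
window, neighbors outside the image dropped (weights renormalize), so
the output is a convex combination of inputs. σ_spatial = 5 px,
σ_intensity = 0.1. The window half-width is ceil(σ_spatial), i.e.
11×11 at the default — a deliberate truncation trading a little tail
mass for a 4× smaller window than a 2σ cut. The filter is implemented
directly (vectorized over the 121 offsets) so its arithmetic is exact;
library variants that quantize the intensity weights through a lookup
table were avoided to keep the operation reproducible to machine
precision. Assigning the ambiguous σ = 5 to the spatial axis and 0.1
to the intensity axis is a documented choice: 0.1 is only meaningful
on a normalized intensity scale.

## Byte rescaling

Min–max affine map onto 0…255, rounded half-up. A constant image maps
to all zeros (it carries no intensity information; zero is the
conventional sentinel). The map is idempotent on byte images that
already span the full range.

## Template matching and structure detection

Matching uses the zero-mean normalized cross-correlation (ZNCC) over
every valid offset, returning the arg-max. ZNCC is invariant to
affine intensity changes — necessary because the ROI is min–max
rescaled while template patches keep their own scale. Raw
(unnormalized) correlation is retained behind `MatchConfig.method =
"ccorr"` for comparison experiments; it is brightness-biased and locks
onto the brightest window, which is why it is not the default. A
zero-variance patch has no defined ZNCC and is rejected.

Fallback variants are tried in a fixed order when the original patch
does not reach the acceptance score: bilinear rescales (defaults 0.9,
1.1), then contrast remaps `clip(128 + c·(p−128))` (defaults 0.8,
1.2). Under ZNCC the contrast variants only matter when clipping
breaks affinity; they chiefly serve the raw-correlation mode. The
acceptance score defaults to 0.60.

Detection is sequential and bidirectional. Top-down: structures in
superficial→deep order, each searched strictly below the previously
accepted interface; bottom-up: the reverse. The band restriction
prevents two structures from locking onto the same bright interface.
The two directional chains are then fused: for every structure the
higher-scoring candidate is preferred, but the selected set must stay
anatomically consistent (interface rows strictly increasing with
anatomical order, consecutive boxes overlapping by at most half the
smaller height). With at most two candidates per structure the best
consistent subset — most structures first, then highest total score —
is found by exhaustive enumeration. The simpler rule "per structure,
keep the higher score unconditionally" was tried first and discarded:
interface templates are visually similar, and a single wrong
high-score lock would evict two correct neighbors during order
validation. `validate_order` applies the same consistency rule as a
final guard and is the only filter applied to externally supplied
detection lists.

A structure that reaches the acceptance score in neither direction is
reported as missing; the measurement record keeps all variables that
remain computable and is flagged incomplete. Missing values are never
imputed.

## Contour refinement

Inside each accepted bounding box the ROI is binarized at the Otsu
level of that box, then cleaned by morphological closing followed by
opening with a disk of radius 2 px (removes speckle-scale specks and
holes without eroding interfaces). The contour is the boundary trace
of the largest connected component; the representative boundary depth
`interface_row` is the median over columns of the component's upper
edge — the median is robust to residual speckle outliers, and the
upper edge is the physically meaningful side because an echogenic band
begins at the acoustic interface and extends into the deeper tissue.
An empty post-morphology mask falls back to the bbox outline, flagged.

## Measurements

- Thickness (Y-axis) variables: difference of consecutive interface
  rows × cm/px. Abdomen: superficial subcutaneous fat (skin/fat
  boundary → superficial fascia), total subcutaneous fat (skin/fat →
  abdominal-wall fascia), peritoneal fat (wall → peritoneal line).
  Thigh: rectus femoris and vastus intermedius between their
  aponeuroses.
- Width (X-axis) variables: the ROI width — the field width fixed
  during initial processing.
- Areas: rectangle height × width for layer-like zones. The
  transverse-plane rectus femoris — the one genuinely elliptical
  cross-section among the measured structures — is fitted with the
  direct least-squares ellipse method: the conic constraint
  4AC − B² = 1 guarantees an ellipse solution, solved in the
  numerically stable partitioned (scatter-matrix) form after centering
  the points; conic coefficients are converted to center, semi-axes
  (a ≥ b) and orientation in [0, π). The fit runs on the refined
  contour of the muscle zone between the two aponeuroses (window
  inset 8 px from the interface bands so Otsu separates muscle from
  cross-section, not band from everything). A failed or implausible
  fit (center outside the zone, axes larger than 1.5× the zone) falls
  back to the rectangle, and the choice is recorded per record in the
  provenance sidecar. Longitudinal scans show layer-like muscle bands
  for which the rectangle is the honest approximation, so ellipse
  fitting is not attempted there.

## Texture features

Gray-level co-occurrence matrices with 32 equal-width levels, offset
distance 1 px, four angles (0°, 45°, 90°, 135°: offsets (0,1), (−1,1),
(−1,0), (−1,−1)), symmetric counting, each matrix normalized to sum 1.
These construction parameters follow common musculoskeletal-ultrasound
texture practice and are configurable. Features per angle, then
averaged: ASM = Σp², contrast = Σ(i−j)²p, dissimilarity = Σ|i−j|p,
homogeneity = Σp/(1+(i−j)²) (inverse-difference-moment form; the
1/(1+|i−j|) dialect is available by config), entropy = −Σp·log₂p over
p > 0 (bits, co-occurrence entropy), correlation =
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) with the degenerate zero-variance case defined
as 0 (no correlation). The histogram variable is the mean of the
normalized 256-bin gray-level histogram, i.e. the pixel mean. Features
are computed on the full preprocessed ROI by default; any sub-window
can be passed instead.

## Agreement statistics

Bland–Altman on auto−manual differences: bias = mean, limits of
agreement = bias ± 1.96·SD (sample SD, n−1; the fixed 1.96 multiplier
is the standard formulation), 95% CI of bias = bias ± 1.96·SD/√n, and
the (mean, difference) pairs are exported for plotting. The precision
score is 100 − MAPE, clipped below at 0, undefined when a reference
value is 0; its 95% CI is a seeded percentile bootstrap (2000
resamples) — the bootstrap is used because no closed form exists for
the clipped statistic.

## Synthetic phantoms

The generator emulates the gross structure of the clinical scans the
pipeline targets: a black transducer-field margin (30 px), horizontal
tissue zones with distinct mean echogenicity, bright interface bands,
an elliptical rectus cross-section in transverse thigh phantoms, and
multiplicative log-normal speckle (σ = 0.25, mean-one normalization)
clipped to bytes. Interface bands start at the true boundary row and
extend into the deeper tissue, so the refined upper contour edge is an
unbiased boundary estimator. Each interface has its own band thickness
and brightness (thick entrance echo at the skin, thin fasciae, broad
peritoneal line) and zones are non-monotone in brightness — mirroring
real contrast between skin, fat, muscle and visceral tissue, and
making interfaces distinguishable by a normalized matcher, which
degenerately uniform bands would not be.

Default geometry (460×520 px at 0.01 cm/px): abdomen interfaces at
rows 80/160/260/360 (superficial fat 0.8 cm, total 1.8 cm, peritoneal
1.0 cm); thigh at 70/130/330/410 (rectus 2.0 cm, vastus 0.8 cm),
transverse rectus ellipse semi-axes 85×130 px (≈3.47 cm²). Cohorts
jitter interface depths (±10 px), intensities (±8) and ellipse axes
(±8 px) uniformly, rejecting and redrawing geometrically invalid
draws; everything is driven by `numpy.random.default_rng` on explicit
seeds, so a (spec, seed) pair fully determines the image bytes. A
generated phantom is checked for band salience (each interface must
remain the row-mean peak of its neighborhood) so that the ROI-scan
premise holds by construction.

Template libraries are extracted from a reference phantom at a seed
disjoint from every analyzed phantom, as patches (21×61 px) centered
on the true interfaces — cut from the bilateral-filtered, rescaled
ROI, i.e. the same representation the detector searches.

A simulated expert reader (truth + Normal(0, σ) noise, default
σ = 0.05 in the variable's units) exercises the agreement module.

What passing on phantoms does *not* show: robustness to curved or
interrupted interfaces, anisotropic speckle, shadowing, probe-pressure
deformation, off-vertical anatomy, or annotation burn-ins — real-scan
features the generator deliberately omits. Results on phantoms bound
the pipeline's numerical correctness, not its clinical accuracy.

## Problem sizes and determinism

The test suite and the reproduction script use 50-phantom cohorts
(25 abdominal longitudinal + 25 transverse thigh) at default speckle,
sizes chosen to estimate the ≥80–90% recovery rates with reasonable
binomial resolution while keeping a full run in tens of seconds. The
pipeline itself contains no randomness: identical inputs and
configuration produce byte-identical measurement CSVs.

## Known limitations

- Interfaces are assumed roughly horizontal within the ROI; strongly
  oblique fasciae would need per-column boundary tracking.
- One elliptical structure per scan category is modeled; the vastus
  intermedius is always measured as a rectangle.
- The X-axis variables equal the ROI width (the field width), not a
  structure-specific extent.
- Raw-correlation matching (`method="ccorr"`) is provided for
  comparison only and is expected to underperform ZNCC.
- The leg-longitudinal subcutaneous-fat thickness (skin/fat boundary
  to rectus aponeurosis) is computable from the detections but not part
  of the default variable set.
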