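# Methods

## Working frame and intensity domain

All processing happens on a fixed 610-row × 407-column portrait frame with
float intensities on [0, 1]. Incoming photographs of any resolution are
bilinearly resampled to exactly that size, stretching if the aspect ratio
differs (the working resolution is fixed by the face template; the
interpolation kernel and aspect policy are this package's own choices, made
for determinism). 8- and 16-bit inputs are divided by their maximum code
value, so threshold arithmetic never depends on camera bit depth. Pixel
coordinates are 0-based `(row, col)`; polygon vertices and ellipse centers
are stored as `(x, y) = (col, row)` floats.

## Contrast filters

Under black light, depigmented skin fluoresces mainly in the blue channel,
somewhat in the green, while the red channel carries overall skin tone.
The four filters (see README for definitions) exploit this. Numerical
choices:

- Filter 2 divides each channel elementwise by blue; wherever B < 1/255
  the divisor is replaced by 1/255 so black background cannot produce
  infinities. Grayscale conversion uses the ITU-R BT.601 luma weights
  (0.2989, 0.5870, 0.1140); note they sum to 0.9999, so a neutral pixel
  (R=G=B) maps to 10⁻⁴, not exactly 0. The complement is taken in float,
  before any quantization.
- Filters 3 and 4 clip negative differences to 0 rather than renormalizing,
  preserving the absolute-intensity semantics the adaptive threshold relies
  on (a renormalization would silently rescale every ROI maximum).
- All outputs are clipped to [0, 1].

## ROIs and adaptive thresholding

An ROI is an implicitly closed polygon with ≥ 3 vertices. Rasterization
sets a pixel iff its center lies inside the polygon under the **even-odd
rule** or on its boundary (tolerance 10⁻⁹, relative to edge length). The
inclusive boundary matches the ≥ comparison used for thresholding. A
polygon that rasterizes to zero pixels is rejected.

Detection runs per ROI: cutoff = global threshold × ROI maximum filtered
value; pixels ≥ cutoff are marked; ROIs combine by union, and a provenance
plane records the first ROI that detected each pixel. Overlapping ROIs
therefore behave like the independent per-ROI loop accumulating into one
image. Degenerate input: an ROI whose maximum gray level is 0 has no
contrast to adapt to; it is skipped with a warning unless the threshold is
exactly 0 (where every ROI pixel is marked by definition). Marking the
whole ROI whenever its maximum is 0 would turn pure-background ROIs into
spurious full detections, which is why the guard exists.

Consequences used by the tests: detection is antitone in the threshold
(masks shrink as T grows), invariant to multiplying the filtered image by
any positive constant, and local (pixels outside all ROIs are irrelevant).

## Face ellipse and registration

The face contour is an axis-aligned ellipse (cx, cy, a, b); its area is
π·a·b and patch burden is reported as set-pixel count over that area.
Registration onto the template maps `x' = round(cx_t + (x − cx_p)·a_t/a_p)`
and analogously for y with the b axes — the horizontal semi-axis drives the
x scale and the vertical one the y scale, the only geometrically sensible
pairing. Rounding is half-away-from-zero, stated explicitly for
cross-language determinism. Points mapping outside the frame are dropped
with a warning rather than clamped: clamping would pile mass on the frame
border and distort the occurrence map. After mapping, the registered mask
is re-binarized so one patient contributes at most 1 to any template cell
even where rounding collapses several source pixels onto one cell;
otherwise a cell of the occurrence matrix could exceed the patient count.
No interpolation-based artifact mitigation is applied; the known rounding
artifact (thin zero-occurrence lines for small cohorts) fades as the cohort
grows.

The bundled template is a generated neutral face raster with ellipse
(cx=203.5, cy=305, a=180, b=280) — fixed but arbitrary; any template can be
supplied via `--template`.

## Occurrence maps and cohort filters

The occurrence matrix is the sum of registered binary masks, expressed as a
percentage of the cohort size, so each cell is an exact multiple of 100/N.
Cohort filters combine by intersection; the onset-to-visit delay is
computed in whole calendar years. Dates may be ISO-8601 or bare years
(anchored at January 1). A criterion referencing a field absent from every
record (e.g. onset age, which requires the optional `onset_age` metadata
column) is skipped with a warning instead of silently emptying the
selection. The rendered map shows the template where occurrence is 0 and
the jet colormap elsewhere, plus a colorbar strip carrying the patient
count; rendering is pure array arithmetic and byte-deterministic.

## Validation metrics

success rate = 100·TP/(TP+FP+FN). The union denominator is chosen because
it is the only reading under which 100% ⇔ perfect agreement and
0% ⇔ disjoint masks, consistent with the green/red/blue overlay partition
(TP/FP/FN). Two empty masks have no lesion and no disagreement; the rate is
defined as 100 with a warning. The threshold sweep runs detection at
n evenly spaced thresholds (default 7 over [0.35, 0.65], i.e. 0.5 ± 30%);
by monotonicity the detecting thresholds for any pixel form a prefix of the
ascending list, and the 100-valued cells equal the detection mask at the
upper endpoint exactly.

## Synthetic scenes and cohorts

The generator emulates the conditions reported from clinical use:

- elliptical face on dark (0.02) background; skin color (0.55, 0.35, 0.30),
  red-dominant as under UV illumination;
- patches as elliptical blobs with additive blue boost 0.3 and green boost
  0.15 (filter-4 contrast margin 0.45 over skin);
- a multiplicative linear illumination gradient, strength 0.2, random
  direction;
- optional overexposed cheek spots (intensity 0.97), beard texture
  (multiplicative noise up to 0.3 in a chin polygon), and dark occlusion
  bars emulating hair strands (intensity 0.03); occluded pixels are removed
  from the ground truth, since occluded skin shows no fluorescence;
- additive Gaussian per-channel noise, σ = 0.01;
- per-scene sessions with one ROI per patch: the patch outline dilated by
  5 px (a 24-gon for elliptical patches), mimicking rough manual
  contouring while giving each patch its own adaptive-threshold region.

Cohorts of n patients jitter the face ellipse per patient but never below
the template's semi-axes, so registration always contracts; a contraction
of the integer pixel grid hits every template cell, which is what makes
designed occurrence regions exact. An `occurrence_design` assigns
rectangular template regions to chosen patient subsets; each designed
patient receives the exact pre-image of the rectangle under the forward
registration map, and random patches are rejection-sampled away from the
designed regions, so the aggregated occurrence over a region is exactly
100·|subset|/n. Default cohort: 3–6 random patches per face (semi-axes
8–20 px, centers within 72% of the face radius so dilated ROIs stay on
skin), 40% chance of an overexposed spot, 30% each of a beard or an
occlusion bar.

What the generator does not model: photorealistic anatomy, camera spectral
response, specular highlights on lesion boundaries, soft patch edges, or
annotation noise in the ROIs (sessions are derived from ground truth).
Passing the simulation surrogate therefore shows that the algorithmic chain
is correct and robust to the modeled nuisances at the stated contrast — not
that clinical accuracy on real photographs is guaranteed.

## Problem sizes

The test suite and the acceptance script run everything at the native
610 × 407 frame; the surrogate validation cohort is 10 patients and the
brute-force oracle comparisons use ≤ 32 × 32 images, sizes at which the
whole suite completes in seconds on one CPU.

## Known limitations

Ellipses are axis-aligned (no head-tilt compensation); no morphological
post-processing of masks; filter choice is manual per patient; the delay
filter resolves whole years only; occurrence maps carry no significance
testing.
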