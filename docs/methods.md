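# Methods

This note documents the model implemented by `bcosfire`, the defaults it
ships with and why, the numerical choices that affect results, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Filter model

The vessel detector is a bar-selective COSFIRE filter: a set *s* of tuples
(σᵢ, ρᵢ, φᵢ), each describing a point at polar position (ρᵢ, φᵢ) around the
filter center at which a rectified difference-of-Gaussians response of
scale σᵢ is expected.  The response is the weighted geometric mean of the
blurred, shifted DoG responses at those points.

**DoG kernel.**  DoG_σ = G_σ − G_{0.5σ}, with each Gaussian normalized to
unit mass *on the discrete kernel grid* (side 2·⌈3σ⌉+1).  Discrete
normalization makes the kernel sum exactly zero despite truncation, so a
constant image produces an exactly zero response.  With the inner Gaussian
narrower, the kernel has a negative center and positive surround: it
responds to *dark* lines, matching vessel polarity in the green channel.
An `invert` switch accommodates bright-vessel inputs.  Borders are handled
by edge replication throughout (convolution, blur, shift); inputs with a
field-of-view mask are additionally padded by replicating the nearest
inside-FOV intensity before filtering so the aperture rim produces no
spurious responses.

**Blur.**  Each response map is blurred with a Gaussian-weighted *maximum*
(not a linear smoothing): D(x) = max over offsets u with ‖u‖∞ ≤ ⌈3σ′⌉ of
C(x−u)·exp(−‖u‖²/2σ′²), σ′ = σ₀ + αρᵢ.  The weight is unit-peak rather
than unit-mass so the σ′ → 0 limit is the identity.  Because the Gaussian
factorizes and the neighborhood is square, the 2-D maximum separates
exactly into two 1-D passes, which is how it is computed.

**Shift and combination.**  Each blurred map is translated by
(−ρᵢ cos φᵢ, −ρᵢ sin φᵢ) — evidence at a configured point moves onto the
filter center; sub-pixel translations use bilinear interpolation.  The
combination is r_s = (Πᵢ Sᵢ^{ωᵢ})^{1/Σωᵢ} with ωᵢ = exp(−ρᵢ²/2τ²) and
τ = max ρᵢ / 3 (floored at 10⁻⁶ so a center-only filter is well defined).
The weights decay with distance from the center — outer points contribute
tolerance, not veto power — while a zero at *any* tuple still annihilates
the product, giving the AND-like selectivity that distinguishes bars from
isolated blobs.  The mean is evaluated in log space; pixels where any map
is zero are set to zero directly.

**Automatic configuration.**  A filter is configured from a drawn prototype
(an antialiased dark bar, or half bar, through the image center): the
prototype's rectified DoG response is sampled on circles of the requested
radii (360 samples, bilinear interpolation), and every circular local
maximum above half the circle's maximum emits one tuple; plateaus of equal
samples are merged at their weighted circular centroid.  A vertical bar
with radii {0, ρ₁, ρ₂} therefore yields five tuples, a half bar three.
Each filter is configured on a prototype of width 2σ *for its own σ* — a
mismatched prototype splits the circle maxima into the bar's two edge
ridges.

**Rotation bank.**  Tuple angles (not kernels) are rotated, so the DoG and
blur stages are computed once per distinct (σ, ρ) and only the cheap shifts
differ per orientation.  The symmetric bar repeats under a half turn, so
its 12 orientations step 15° across [0°, 180°); the half bar must catch
endings in every direction, so its 12 orientations step 30° across
[0°, 360°).  Orientation responses are combined by pixelwise maximum.  The
combined vessel-likelihood map is sym/max(sym) + w·asym/max(asym) with
w = 0.5 by default: the bar response carries the segmentation and the
half-bar response reinforces endings without being allowed to dominate the
interior scoring; both the weight and the choice of summation (rather than
a pixelwise maximum) are exposed as parameters.

## Defaults and their rationale

| parameter | default | rationale |
|---|---|---|
| σ (bar) | 2.4 px | matched to vessel widths of roughly 2–7 px (DRIVE-scale imagery and the default phantoms) |
| σ (half bar) | 1.8 px | slightly finer scale localizes endings better |
| ρ set | 0…8 (bar), 0…12 (half bar), step 2 | support long enough to enforce elongation without bridging across gaps |
| σ₀, α | 0.5, 0.1 | keeps the 30 %-of-max lateral profile within ~1 px of the true vessel edge while still tolerating the ~1 px excursions of a 15°-quantized bank; larger σ₀ measurably fattens segmented vessels |
| orientations | 12 | 15° quantization costs < 1 % of the response maximum between orientations |
| preprocessing threshold | 0.3 | center of its 0.1–0.6 search range |
| filter threshold | 30 % | center-low of its 25–50 search range |
| t (response suppression) | 0 | thresholding is deferred to binarization, which uses the same fraction-of-maximum rule |

The filter threshold is carried on its integer percent scale (25–50) and
divided by 100 where a fraction is required; response suppression and
binarization are both *relative to the global response maximum*, so the
parameters transfer across images of different contrast.  The
preprocessing threshold is applied to each rectified DoG map as a fraction
of that map's own maximum, before the combination stage.

## Postprocessing semantics

Foreground components use 8-connectivity, background holes 4-connectivity
(the standard duality).  Component filtering deletes components with area
*strictly below* the artifact size — consistent with the search range
starting at 0 and making sizes 0 and 1 identities.  The 2-median variant
clusters component areas with deterministic extreme-value initialization
(centers at the minimum and maximum area, ties to the low cluster) and
deletes the low cluster only when its median area falls below the artifact
size; single-component and equal-area masks pass through unchanged.
Black-and-white clearance fills holes of area strictly below the hole
size, which defaults to half the artifact size.

## Optimization and ANOVA

Grid search evaluates the full Cartesian product of the parameter grid on
an evaluation split (deterministic seeded shuffle, default 50/50).
Aggregate metrics sum confusion counts over images before deriving
sensitivity / specificity / accuracy, and evaluation is restricted to the
FOV when masks exist.  Selection maximizes accuracy with ties broken by
higher sensitivity, then higher specificity, then the lexicographically
smallest parameters — a deterministic, permutation-stable rule.  The rule
is pluggable; on the published DRIVE experiment records it reproduces the
published best combination exactly.

The ANOVA screen treats each grid record (one parameter combination's
aggregate metrics) as one observation and groups records by the levels of
one parameter, marginalizing over the others.  These groups are not
independent samples — the classical one-way F-test is reported regardless,
as a screening device for which parameters move the metrics at all; no
multiple-testing correction is applied across the nine parameter × metric
cells.  Zero within-group variance is reported as a flagged degenerate
result (F = ∞, p = 0 when the means differ) rather than an exception.

## Phantom generator

Phantoms emulate the features the pipeline is sensitive to: a bright
field-of-view disc (radius 0.46·min(h, w)) on a dark surround, a mild
diagonal illumination gradient (±5 %), vessels as smooth random-walk
centerlines with a Gaussian cross profile (FWHM = nominal width, drawn
from 3–6 px at contrast 0.5), dark background blobs of exactly 4–18 px
area placed strictly disjoint from the vessels, and additive Gaussian
noise (SD 0.02).  The ground truth is the region where the vessel
darkening exceeds half its peak, so mask width equals nominal width;
artifact areas are exact by construction (the *n* nearest pixels to a
center), giving artifact-size recovery a well-defined answer.  Everything
is a deterministic function of the seed.

What phantoms do **not** emulate: central vessel reflex (available as an
optional flag, off by default), branching and crossing topology,
pathologies (hemorrhages, exudates, drusen), JPEG artifacts, and realistic
texture.  Passing the phantom suite therefore demonstrates correctness of
the machinery and sane parameter recovery under the stated conditions, not
clinical-grade performance on fundus photographs.

## Problem sizes

The shipped tests and the acceptance script run the default suite at six
256×256 phantoms (roughly the vessel-width-to-image-size ratio of
downsampled fundus imagery), a 160×160 four-phantom suite for the
grid-vs-oracle comparison, and the full default grid of
6 × 26 × 6 = 936 combinations with the component filter; these sizes were
chosen so a complete run finishes in well under a minute on one core while
every stage (including the 936-point search) is exercised end to end.

## Known limitations

- Only rotation tolerance is implemented; the scale- and
  reflection-invariant generalizations of COSFIRE filtering are out of
  scope, and σ must be chosen to match the imagery's vessel widths (no
  multi-scale analysis).
- The half-bar/bar combination weight and the blur law were fixed against
  synthetic bars and phantoms; on real datasets they are worth re-tuning
  (both are constructor parameters).
- The ANOVA observations are correlated by construction (shared images,
  shared marginalized parameters); p-values should be read as screening
  indicators, not confirmatory inference.
- STARE ships no FOV masks; `make_fov` can estimate one from brightness,
  but no claim is made that this matches any published protocol.
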