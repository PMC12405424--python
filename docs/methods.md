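# Methods

## Scene and model

The target scene is a strip-intercropped field: tall maize strips
alternate with six-row soybean strips, rows instrumented at l = 30, 60,
90, 120, 150, 180 cm across the soybean strip. The maize canopy shades
the soybean strip from the south, so nadir images show brightness rising
from the left (south, shaded) edge to the right (north) edge. All image
operations in this package assume that orientation.

Two layers describe the light field:

1. **Physical identities.** Direct illuminance E = E₀·cos θ (θ = solar
   elevation, degrees), diffuse E₀·Df with Df ∈ [0.1, 0.2] on clear
   days, reflected E₀·α with α = 0.1 for a soybean row, and total shaded
   illuminance E₀·(cos θ − f) + E₀·Df + E₀·α. These are implemented as
   published for this scene, including two deliberate oddities: the
   direct term uses cos of the *elevation* angle (standard horizontal
   irradiance would use sin), and shadow length is h·tan θ
   ("as-written" mode) although flat-ground geometry gives h/tan θ — a
   "geometric" mode provides the latter, and the two multiply to h² as a
   cross-check. The attenuation term f(h, d) has no published closed
   form, so callers pass its value directly (default 0); the fitted
   polynomial supersedes this identity in the image pipeline.

2. **Empirical surface.** y(h, θ, l) is a full quadratic (ten terms,
   coefficients a0…a9 in the fixed order 1, h, θ, l, h², hθ, θl, θ²,
   hl, l²). Angles enter in degrees: the shipped coefficient vector is
   only meaningful with degree-valued inputs, matching the field tables
   it was fitted to. Intensities are in "instrument units" — the
   illuminometer's scale; no lux conversion is attempted (the intercept,
   ~3.1×10⁶, is not a plausible clear-sky lux value, so the model is
   honored on its own scale).

### Fitting

`fit_polynomial` solves ordinary least squares on the ten-column design.
Columns span ~8 orders of magnitude (1 vs l² = 32 400), so the design is
column-normalized before an SVD solve; the solution is unchanged, the
conditioning is not. Rank is checked first via pivoted QR; a deficient
design raises an error naming the non-identifiable terms rather than
silently returning a pseudo-inverse, because a wrong surface propagates
directly into image compensation. Noise-free recovery on the full-rank
calibration grid is exact to ~1e-12 relative.

One practical consequence surfaced by the rank check: the five observed
growth stages pair h with θ (five (h, θ) points), which can identify at
most five of the six pure-(h, θ) terms. Identification requires the
h × θ cross product, which the synthetic measurement generator and the
acceptance harness use.

## Column-wise compensation

For an image of width W, columns map linearly onto l ∈ [30, 180] cm
(the instrumented row span; configurable). The surface predicts a target
illuminance per column; the reference defaults to the brightest column's
prediction (policies: brightest-column, mean-column, fixed value). Each
column's pixels are multiplied on all three channels by
clamp(reference/target, 0.5, 1.2), rounded half-away-from-zero and
clipped to [0, 255].

Design choices where the published description is silent:

* **Ratio orientation** — reference/target, so shaded (low-prediction)
  columns brighten; this reproduces the reported behavior (shaded-side
  brightness rising, bright side nearly unchanged).
* **Reference** — the brightest column, so compensation only brightens
  (up to the clamp) and never dims the sunlit side.
* **Normalization** — clipping to [0, 255], not min–max rescaling,
  which would undo the absolute brightening the method exists for.
* **Equal per-channel scaling** — preserves hue exactly up to rounding;
  verified to ≤2 hue degrees on unclipped, chromatic pixels.
* **Rounding** — half away from zero, fixed so outputs are
  bit-reproducible across platforms.
* **Nonpositive predictions** — the shipped quadratic dips below zero
  near the shaded edge at the largest height difference (h = 113,
  θ = 27: y(30) ≈ −12 315). A ratio against a nonpositive target is
  meaningless, so `compute_ratios` rejects such inputs; the composed
  `icnet_enhance` instead treats them as maximally dark and applies the
  clamp ceiling — the limit of reference/target as the target
  approaches zero from above. Emitted ratios therefore always lie in
  [0.5, 1.2] for any coefficient vector.

### What the clamp can and cannot fix

The clamp bounds correction at ×1.2. A shading floor of s requires
×(1/s); for s < 1/1.2 ≈ 0.83 the residual brightness error at the
darkest column is at least 1 − 1.2·s (28 % at s = 0.6). On synthetic
scenes with a 0.6 floor this caps PSNR against the uniformly lit truth
near 22–23 dB regardless of the target profile — the compensation
reliably *improves* PSNR (≈ +5 dB) and outperforms the baseline
enhancers, but cannot reach the conventional 30 dB
high-reconstruction-quality bar. Relatedly, because the synthetic
shading field is an affine rescale of the surface while the ratio
inverts proportional shading, the corrected column-mean gradient
flattens only partially when the clamp binds over most of the image;
full flattening holds when predictions are positive and shading is
proportional to them (the regime the gradient-flattening test uses).

## Baselines

* **Histogram equalization** — classical CDF remap per channel,
  T(v) = round(255·(cdf(v) − cdf_min)/(1 − cdf_min)); a constant channel
  is left unchanged. Per-channel (not luminance) application is
  intentional: it reproduces the strong color shifts this method is
  known for on canopy images.
* **Multi-scale Retinex** — per channel, Σᵢ wᵢ·[log(I+ε) − log(Gσᵢ*I+ε)]
  with normalized Gaussian surrounds (scipy, nearest-edge padding),
  ε = 1 on the 0–255 scale, default scales {15, 80, 250} px with equal
  weights (standard practice; no scales are published for this scene).
  The log-reflectance is min–max rescaled per channel to [0, 255]; an
  all-equal field maps to 0. Images smaller than the largest surround
  warn and proceed with a border-truncated kernel.
* **Gamma correction** — round(255·C·(v/255)^γ), default γ = 0.8, C = 1
  (γ < 1 lifts the dark regions, the relevant direction here).

## Evaluation

MSE averages squared differences over all pixels and all three channels
jointly (m·n·3 denominator), computed in wide arithmetic. PSNR =
10·log₁₀(255²/MSE), +∞ sentinel for identical images. Centerline
profiles sample row ⌊H/2⌋ in RGB or HLS; HLS uses the hexcone model
with H in degrees [0, 360) (undefined hue reported as 0) and L, S
rescaled to [0, 255] — a fixed convention chosen so profile axes are
comparable across channels; the conversion matches stdlib `colorsys`
and round-trips within ±1. Optional profile smoothing is a centered
moving average with edge truncation. Channel standard deviations are
population (ddof = 0) statistics over all pixels after discarding
⌊W/10⌋ columns at each side, where the strip borders dominate.

## Synthetic scenes

`generate_canopy_image` emulates a nadir soybean-strip photograph:

* **Texture (ground truth)** — two seeded smoothed-noise layers shared
  across channels (coarse canopy structure, σ = 25 px, sd 18; fine leaf
  speckle, σ = 2 px, sd 10) around green-dominant channel means
  (R, G, B) = (140, 190, 120), echoing the reported field ranges (green
  150–230 above red/blue 120–200). The generator contract keeps the
  green mean strictly above red and blue.
* **Shading** — multiplicative on the texture (the reflectance ×
  illumination image-formation model). The per-column factor is the
  quadratic surface evaluated at the column positions, affinely rescaled
  so the brightest column keeps 1.0 and the darkest gets `shade_floor`
  (default 0.6); instrument units have no absolute mapping onto 8-bit
  pixels, so only the profile's shape is used, and the rescale is
  recorded and invertible. Optional Gaussian pixel noise is added after
  shading.

Everything is deterministic under the seed. What these scenes do *not*
emulate: real leaf geometry and specular highlights, row furrows,
within-column illumination variation, camera response nonlinearity, and
JPEG artifacts — so passing tests demonstrate the algorithmic contracts
and relative method ranking under the stated image-formation model, not
field performance.

Synthetic measurement tables draw y(h, θ, l) plus i.i.d. Gaussian noise
at caller-specified sd; three readings per row mirror the field
protocol.

## Problem sizes and defaults

The test suite runs scenes at 64–256 px widths for speed and the
end-to-end comparison at 512×512 over 20 seeds; the acceptance script
uses the 150-point calibration grid and the same 20-scene, 512×512
comparison. Defaults throughout: clamp [0.5, 1.2]; column span
30–180 cm; shade floor 0.6; measurement noise 0 unless requested;
E₀ = 1, δ = 0, Df = 0.15, α = 0.1 for the shipped stages (h and θ are
the five observed stage values; the other four parameters are not
tabulated per stage, so neutral defaults are shipped: unit direct
intensity, rows along the reference axis, mid-band diffuse fraction,
the stated soybean-row reflectance).

## Known limitations

* The shipped coefficient vector predicts negative illuminance near the
  shaded edge at the largest height difference; the compensation handles
  this (clamp ceiling) but the surface itself should not be trusted
  outside l ∈ [30, 180] cm or far from the observed (h, θ) pairs (an
  extrapolation warning fires outside the calibrated l range).
* The clamp bounds achievable correction (see above); deep shadows
  remain under-corrected by design.
* Column-wise correction assumes shading varies only with l; real
  canopies also vary along rows.
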