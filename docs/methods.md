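# Methods

## The shape model

A lanceolate leaf blade is modeled as a closed polar curve

    r(φ) = l · (|cos(φ/4)| + |sin(φ/4)|)^(−1/n),      φ ∈ [−π, π),

a two-parameter special case of the Gielis superformula
r(φ) = [|cos(mφ/4)/a|^{n₂} + |sin(mφ/4)/b|^{n₃}]^{−1/n₁}
obtained by setting m = 1, a = b = 1, n₂ = n₃ = 1, n₁ = n.  The kernel has
period 2π and is even in φ, so the modeled outline is mirror-symmetric
about the tip–base axis by construction, with the tip at φ = 0 (r = l) and
the base at φ = ±π (r = l·2^(−1/(2n))).

Parameters:

- **l** (cm, > 0): the distance from the polar origin to the leaf tip.
  Sets absolute size only.
- **n** (dimensionless, > 0): the leaf-shape parameter.  It fixes every
  size-free property of the outline, in particular the width-to-length
  ratio; small n gives narrow, linear-lanceolate blades, larger n broader
  ones.  Lanceolate foliage leaves fall in roughly n ∈ [0.01, 0.2];
  values outside this range warn but are not rejected.

Derived functionals:

- **Length** L = (1 + 2^(−1/(2n)))·l, the sum of the tip and base radii —
  closed form, no integration.
- **Width** W = 2·max_{φ∈[0,π]} r(φ)·sin(φ), the maximal extent
  perpendicular to the tip–base axis, found by bounded scalar
  maximization (`xatol` 1e−12).  The objective is smooth on (0, π): the
  kernel's only kink is the acuminate tip at φ = 0, where the objective
  vanishes.
- **Aspect ratio** W/L, a function of n alone (both W and L are linear
  in l).
- **Area** A = ½∫r² dφ, computed as ∫₀^π r² dφ by adaptive quadrature
  (relative tolerance 1e−10) using the evenness of r; integrating on the
  half-range never crosses the tip's slope discontinuity.

A subtlety worth recording: the tip-to-base length L equals the outline's
x-extent only for n ≥ 1/16.  For smaller n the curve bulges slightly
*behind* the base point (x is not minimized at φ = π), by up to ≈3×10⁻⁵·L
near n ≈ 0.04.  Length-from-boundary measurements (convex-hull diameter)
therefore agree with the closed form to ~5×10⁻⁵ relative, not machine
precision; tests assert the identity through the tip and base points
themselves and document the extent bound separately.

Angle reduction uses φ − 2π·round(φ/2π).  Because `round` is odd, the
reduction commutes with φ → −φ bit-exactly, so r(φ) = r(−φ) holds to
machine equality, not merely approximately — the property the symmetry
test leans on.

## Fitting

A digitized boundary is matched to the model by estimating five
parameters jointly: (l, n) and a rigid pose (x₀, y₀, θ) — the polar
origin and the rotation of the tip axis — since a scanned leaf never sits
at the model frame's origin.  Each observed point is pose-normalized,
x′ = (x−x₀)cosθ + (y−y₀)sinθ, y′ = −(x−x₀)sinθ + (y−y₀)cosθ, converted
to (φᵢ, rᵢ), and the objective is the sum of squared **radial** residuals
Σ(rᵢ − r(φᵢ; l, n))².  Radial residuals (rather than point-to-curve
distances) keep the objective cheap, smooth almost everywhere, and make
R² on radii a direct measure of boundary agreement.

Optimization is Nelder–Mead over (log l, log n, x₀, y₀, θ); the log
transform enforces positivity without constraints.  Tolerances: function
tolerance 1e−10 × the objective at the start, parameter tolerance 1e−8,
at most 5,000 iterations.  Two deterministic starts are always run — the
initialization below and its tip/base flip (θ + π), since the model is
not tip/base symmetric — keeping the lower residual; up to 4 seeded,
jittered restarts are attempted only if neither start converges to a
credible optimum (R² < 0.9).  Fits are fully deterministic given the
curve and options.

Initialization: origin at the boundary centroid; tip = farthest point
from the centroid (exact ties broken by lowest index); θ from centroid to
tip; l = that distance; n = 0.06, the midpoint of the lanceolate range.
Fitting refuses boundaries spanning less than 3π/2 of angle around the
initial origin (not a closed outline).

Goodness of fit is R² = 1 − RSS/TSS on radii.  Because the model is
exactly mirror-symmetric, R² doubles as the bilateral-symmetry measure:
a blade with a one-sided deformity cannot be fit well by any symmetric
curve, so R² strictly drops relative to a symmetric control with the
same noise (verified at bulge amplitudes of 2% and 5% of l).

θ is reported wrapped to (−π, π].

## Boundary extraction

Scans are binarized with Otsu's threshold (or a fixed value); foreground
polarity is resolved automatically as the class occupying less of the
image border, since a leaf never wraps the frame.  Holes are filled and
only the largest connected component survives.  The contour is traced by
marching squares at the 0.5 level — sub-pixel, through midpoints between
foreground and background pixel centers, which removes the half-pixel
dilation bias of pixel-edge tracing — then resampled uniformly by arc
length (default 2,000 vertices), oriented counter-clockwise, flipped to
mathematical axes (y up, origin lower-left) and scaled to cm.  Extraction
is deterministic.  Blade length from a boundary is the convex-hull
diameter.  Petioles/pseudo-petioles are not segmented; real scans must
present the blade only, a documented limitation.

## Synthetic data

The generator emulates the survey protocol on which the method is used:
per species, a Weibull(k, λ) leaf-length sample (lengths of foliage
leaves are right-skewed, Weibull rather than normal); the leaves nearest
the median length are "digitized" as model boundaries whose scale l is
back-solved from the target length through the length identity,
l = L/(1 + 2^(−1/(2n))).  Each boundary applies, in order: multiplicative
radial noise rᵢ = r(φᵢ)(1 + εᵢ), εᵢ ~ N(0, sd²), emulating digitization
error; an optional one-sided raised-cosine bulge δ·l over a configurable
arc on the φ > 0 side only — a smooth, parameterized symmetry violation
used purely as a test instrument; and a random rigid pose.  Defaults:
500 lengths per species, 30 digitized leaves per species, radial noise
sd = 0.5% — the scale of digitization error consistent with the
near-perfect fits the method is known to produce on real lanceolate
leaves.

Rasterization to scan-like masks uses an even-odd scanline fill that
marks a pixel foreground iff its **center** lies inside the polygon;
center-based filling keeps the rasterized area unbiased, so the
render→extract round trip converges as resolution grows (area error
≈0.1% at 150 dpi-equivalent, ≈0.03% at 300 dpi, ≈0.007% at 600 dpi for a
10-cm blade).

Seeding: per-species and per-leaf generators derive from
`SeedSequence(master_seed, spawn_key=(species_index, leaf_index))`, so a
single leaf is reproducible without regenerating the panel, and the same
configuration always produces a byte-identical manifest.

What the generator does **not** emulate: venation, texture, shadows,
petioles, scanning artifacts (dust, skew, JPEG noise), or biological
asymmetry structure beyond the single smooth bulge.  Passing tests show
the estimator and pipeline are correct and well-calibrated on
model-shaped data, not that real scans of any particular taxon satisfy
the model.

## Population statistics

- **Normality / Weibull testing of lengths.**  Shapiro–Wilk for
  normality; for the Weibull hypothesis, a maximum-likelihood fit
  followed by a one-sample Kolmogorov–Smirnov test.  The Weibull MLE
  profiles the scale out analytically — λ̂(k) = (mean xᵏ)^(1/k) — leaving
  one monotone equation in k, Σxᵏln x/Σxᵏ − 1/k = mean(ln x), solved by
  Brent's method (all moments computed with a log-shift for overflow
  safety).  Convention: CDF 1 − exp(−(x/λ)ᵏ).
- **KS p-values.**  The default p treats the fitted Weibull as fully
  specified; with estimated parameters this is anticonservative (it
  under-rejects), which is acceptable when the test is used, as here, to
  *fail to reject* the Weibull.  Where calibration matters a parametric
  bootstrap is provided: refit on each of B resamples from the fitted
  distribution, p = (1 + #{D_b ≥ D})/(B + 1); with B = 199 this holds
  its 5% size (verified over 500 replicates).
- **Representative-leaf selection.**  The k lengths nearest the sample
  median (even-size median = mean of the central order statistics), ties
  to the lower index; a warning if any selected leaf deviates from the
  median by more than the tolerance (default 5%).
- **Cross-species comparison.**  Tukey's HSD on per-leaf n̂ values in a
  one-way layout (Tukey–Kramer for unequal sizes), adjusted p-values
  from the studentized-range distribution; a species' point estimate is
  the mean of its per-leaf n̂.  With exactly two groups the procedure
  reduces to the pooled-variance t-test (q = √2·|t|), which the tests
  verify to 1e−10.
- **Area agreement.**  OLS of model-predicted areas (polar integral at
  the fitted parameters) on observed polygon (shoelace) areas.  Perfect
  prediction is the identity line: slope 1, intercept 0.  Both the
  analytic integral and the polygon area of the fitted curve are
  available as predictions; the analytic integral is the default.

## Problem sizes used in the shipped checks

Simulation sizes were chosen to give stable verdicts at interactive
cost: noiseless recovery on a 5×5 (l, n) grid; 100 replicates for the
noise-robustness and symmetry-sensitivity checks; 100-leaf panels for
the area identity line; 1,000 replicates for Shapiro–Wilk size and
power at sample size 500; 500 replicates (B = 199) for bootstrap-KS
calibration; the acceptance script fits 6 species × 30 leaves.

## Known limitations

- The model is for entire, lanceolate-to-broadly-lanceolate blades;
  orbicular, cordate or hastate outlines need the general superformula
  (out of scope here beyond the reduction identity).
- Only the symmetric two-parameter model is fitted; asymmetric leaves
  are *detected* (via depressed R²), not modeled.
- Real-scan preprocessing (petiole removal, color correction,
  multi-leaf sheets) is out of scope.
- The plain KS p-value with estimated parameters is anticonservative;
  use the bootstrap when the conclusion depends on it.
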