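# Methods

## Forward models

Speckle contrast is `K = σ/I` over a small sliding window; all model
equations are written in `K²`. For a field autocorrelation
`g₁(τ) = exp(-(τ/τc)ⁿ)` and a detected intensity that mixes a dynamic
fraction `ρ` with static scattering, the time-integrated variance gives

    K²(T) = β [ ρ² F₂ₙ(x) + 2ρ(1-ρ) Fₙ(x) + (1-ρ)² ],   x = T/τc,

where `Fₐ` is the triangular-window integral
`(2/T)∫₀ᵀ (1-τ/T) e^{-a (τ/τc)ⁿ} dτ`. Two exponents are implemented:

- **multiple-ordered** (`n = 1`, aligned flow in arterioles/venules —
  "vessel" model): `F₂ = (e^{-2x} - 1 + 2x)/(2x²)`,
  `F₁·2 = 4(e^{-x} - 1 + x)/x²`;
- **multiple-unordered** (`n = ½`, unaligned capillary flow —
  "parenchyma" model): with `s = √x`,
  `F₂ = (e^{-2s}(4x + 6s + 3) + 2x - 3)/(2x²)`,
  `F₁·2 = 8(e^{-s}(2x + 6s + 6) + x - 6)/x²`.

The mixed model interpolates linearly between the two with the weight
`d_mu ∈ [0, 1]` (0 = pure vessel, 1 = pure parenchyma). Both closed
forms and their analytic `dK²/d ln T` were derived symbolically and are
verified in the test suite against direct numerical quadrature of the
defining integral (≤ 1e-6 relative) and against finite differences.

Single-scattering from ordered motion (`n = 2`) is not modelled: the
photon mean free path is far shorter than the vessels where it would
apply. The additive nonergodic noise constant is likewise omitted
(negligible for low-noise sensors).

**Numerics.** The `(…)/x²` forms cancel catastrophically at small `x`;
below `x = 10⁻³` (in `s` for the unordered model) evaluation switches to
5-term Taylor series generated with sympy. The threshold keeps both
branches below ~1e-12 relative error; at the often-quoted switch point
of 1e-6 the direct branch would already carry ~1e-4 cancellation error.

## The quasi-analytic estimator

The estimator exploits three limits of the mixed model —
`K²(T→0) = β`, `K²(T→∞) = β(1-ρ)²`, and the critical contrast
`K²crit = K²(T=τc)` (the mixed model evaluated at `x = 1`) — and solves
the parameters in a fixed order:

1. **Filter.** `K²(T)` is smoothed along the exposure axis: a 1:4:1
   weighted moving average (replicate-padded) for log-uniform ladders; a
   weighted *local-linear* smoother (inverse-`ln T`-distance weights in a
   ±⅓-decade window) for irregular ladders. The local-linear form is
   essential at the ladder ends: a plain weighted average is first-order
   biased on its one-sided boundary windows, which flattens the tail
   slope and breaks the slow-flow half of the benchmark.
2. **Differentiate.** Centered differences over `ln T`, attributed to
   midpoints, smoothed again (3-point average, or local-linear with
   one-decade width for irregular ladders). `K²` is resampled onto the
   midpoint positions (linear in `ln T`).
3. **Locate the peak.** The most negative derivative sample and its
   neighbors define a quadratic (Newton) polynomial whose vertex gives
   `T_peak`; the polynomial value there, raised 5% to compensate filter
   attenuation, gives the peak amplitude. `T_peak` lies between ~0.8 τc
   and ~3.3 τc depending on `ρ` and the scattering model. The vertex may
   extrapolate up to one decade beyond the sampled range; if the minimum
   sits at a ladder end with a degenerate/concave local quadratic, the
   peak is placed one decade past that end. Without this, pixels whose
   true peak lies outside the ladder collapse to `ρ ≈ 0` and the
   recovered flow diverges instead of saturating.
4. **Extrapolate the limits.** With `γ = T/T_peak`, the ratios
   `B₀(γ) = dK²/(β - K²)` and `B∞(γ) = dK²/(K² - β(1-ρ)²)` are
   nearly `ρ`-independent, so the first and last samples extrapolate to
   `β = K² + dK²/B₀` and `β(1-ρ)² = K² - dK²/B∞`;
   `ρ = 1 - √(lim∞/lim₀)`.
5. **Assign the scattering model.** The compensated peak amplitude is
   placed between the theoretical minima of `dK²/d ln T` for the two
   models (degree-10 polynomials in `ρ`, scaled by `β`), giving `d_mu`
   clamped to [0, 1]. Limits and `ρ` are then re-estimated with the
   assigned weight.
6. **(sREMI) Smooth β.** `β` varies slowly across a field of view
   (aberrations, defocus), so the β map is Gaussian-filtered (default
   kernel 10% of the smaller image dimension, σ = half the kernel,
   reflective borders) and the model assignment is repeated with the
   smoothed zero-exposure limit.
7. **Interpolate τc.** `K²crit` follows from the final `(β, ρ, d_mu)`;
   where `ρ < 0.2` it is capped at `β/2` to avoid falsely high flow from
   near-flat curves (in practice the cap engages only for essentially
   static scenes). `log τc` is linearly interpolated between the last
   exposure with `K²` above `K²crit` and the next; if the whole curve
   stays above, the last two exposures extrapolate, and if the first
   sample is already below, the first two do. Recovered `τc` is confined
   to one decade beyond the ladder: values at those rails mean "outside
   the supported range", not a resolved measurement. Flat-curve pixels
   (`|dK²| < 10⁻⁶·max K²`) are flagged static rather than estimated.

The cap is conditional on `ρ < 0.2` deliberately: for the vessel model
`K²crit/β ∈ [0.57, 1.0]` at *every* `ρ`, so an unconditional
`min(K²crit, β/2)` would bias every vessel pixel.

### Empirical helper curves

Two ingredient families are generated from the forward models (not
transcribed) and cached with their generation grids in
`src/mesi/data/empirical.json` (`scripts/generate_empirical.py`
rebuilds it):

- **Peak-amplitude polynomials** — degree-10, origin-constrained fits in
  `ρ` (grid step 0.005) to the bounded 1-D minimization of the analytic
  derivatives at `β = 1`; agreement with direct minimization ≤ 1e-7.
- **Boundary-ratio expansions** — for each model, `B₀` and `B∞` are
  rational functions of `√γ` under a square root (second-order-filter
  magnitude forms) with the exact `γ→0` limits (−1 vessel, −½
  parenchyma) and `B∞(γ→∞) = −1` enforced; coefficients are fitted to
  the exact ratios by iteratively reweighted least squares on the log
  magnitude, pooled over `ρ ∈ [0.5, 1]`. Fit windows match usage:
  `γ ∈ [10⁻², 10]` for `B₀` (consumed at `T_first/T_peak`),
  `γ ∈ [10⁻², 10²]` for `B∞`. Achieved worst-case errors: 5.4%/6.9%
  (`B₀`, vessel/parenchyma) and 4.0%/9.5% (`B∞`). These residuals are
  close to the intrinsic `ρ`-misalignment of the exact curves under the
  `T/T_peak` scaling, so they are a property of the method, not of the
  fit; beyond `γ ≈ 10` the parenchymal `B₀` curves no longer align at
  all (18–34% spread), which is why the fit window stops there.

The residual `B∞` error concentrates the estimator's `ρ` error at low
flows, where `β(1-ρ)²` is small and the extrapolation is most sensitive
— mirroring the known behavior of the method on real data.

## Reference least-squares fitter

Per-pixel bounded trust-region least squares in `K²` space with
`τc` optimized as `log₁₀ τc`; bounds `β ∈ (0, 1.05]`, `ρ ∈ [0, 1]`,
`τc ∈ [10⁻⁸, 10²] s`, `d_mu ∈ [0, 1]`. Initialization is data-driven
(`β₀ = max K²`, `ρ₀ = 1 - √(min/max)`, `τc₀` from the single-exposure
flow estimate at the mid-ladder exposure, `d_mu₀ = 0.5`) with two
deterministic restarts shifting `τc₀` one decade either way; restarts
are skipped once a start reaches a residual sum of squares below 1e-9
(far below any noise floor). Jacobians are analytic: `β` and `d_mu`
enter linearly, the `ρ` partial follows from the quadratic parameter
structure, and the `log τc` partial is the negated semilogarithmic
derivative. Flat curves (`ρ → 0`) are flagged unidentifiable rather
than fitted. The soft `β ≤ 1.05` bound tolerates noise pushing the
zero-exposure limit above 1.

## Synthetic data and what it does not contain

The simulator evaluates the forward models exactly on parameter grids
(the benchmark grid: 101 log-spaced `1/τc ∈ [10⁰, 10⁵] s⁻¹` × 26
`ρ ∈ [0.5, 1]`, `β = 1` — the accuracy metric is insensitive to the
choice of β, which scales out of the curves) and on spatial phantoms
(smooth β bump ≤ 30% relative variation, vessel stripes `d_mu = 0` with
`τc = 0.2 ms` on a parenchymal background `d_mu = 1`, `τc = 2 ms`).
Noise is multiplicative uniform on `K²`: `K²(1 + U(-f, f))`, default
`f = 0.05`, seeded. Two exposure ladders are provided: 20 log-spaced
exposures (20 µs – 650 ms) and an editable "typical" 15-step irregular
ladder (50 µs – 80 ms) following the 1–2.5–5 convention of the MESI
literature.

Synthetic curves contain *no* shot/read noise, no speckle sampling
statistics from finite contrast windows, no frame-to-frame physiology,
and no spatial correlation of noise. Passing benchmarks therefore
demonstrates correctness and the intrinsic accuracy ordering of the
methods under the stated noise model, not instrument-level performance.

## Evaluation conventions

`logspace_r2` pools all pixels: coefficient of determination (or squared
Pearson) between `log₁₀` truth and `log₁₀` estimate, invalid pixels
excluded, constant estimates defined as 0. `trace_r2` first averages the
log estimates over the `ρ` axis at each true flow value — the
method-comparison traces — and correlates that trace with `log₁₀`
truth. The reference correlation matrix is reproduced under the trace
convention; pooled metrics are reported alongside in every benchmark
table. Wrong-model fits (simple model on unordered-scattering data)
carry a large smooth log-bias, so their pooled determination coefficient
is low even where the trace correlation is high — both numbers are
informative and both are emitted.

## Known limitations

- The irregular-ladder nonuniform filter is a documented stand-in
  (inverse-distance local-linear); published instrument-specific
  weightings differ in detail. Accuracy on the irregular ladder under
  noise is a few points below the log-uniform ladder.
- `ρ` error concentrates at the low-flow end of the supported range
  (boundary-extrapolation sensitivity, see above) and the estimator
  underestimates `β` when `τc` falls near or below the shortest
  exposures; sREMI substantially repairs the latter.
- Estimates saturate one decade beyond the exposure ladder by design;
  flows outside `[1/(10·T_max), 10/T_min]` are reported at the rails.
- The least-squares fitter matches the generating parameters on clean
  in-range curves but is not bit-compatible with any particular
  published optimizer trajectory.
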