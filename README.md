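# mesi — multi-exposure speckle imaging analysis

Laser speckle contrast imaging (LSCI) maps tissue perfusion from the
blurring of a laser speckle pattern: moving red blood cells decorrelate
the scattered field, and the local contrast `K = σ/I` of a time-integrated
image drops as the exposure time `T` grows past the field correlation time
`τc` (1/τc is the flow index). Multi-exposure speckle imaging (MESI)
records a ladder of exposure times and fits the full `K²(T)` curve, which
separates true flow from the confounds that make single-exposure LSCI
qualitative: source coherence and speckle/pixel-size mismatch (the
normalization `β`), static tissue scattering (the dynamic-scattering
fraction `ρ`), and the scattering regime (ordered motion in vessels vs
unordered motion in parenchymal capillary beds, mixed by a weight `D_MU`).

The bottleneck of MESI is the per-pixel nonlinear fit — minutes to hours
per frame. This package implements, alongside the conventional fit, a
**quasi-analytic estimator (REMI — rapid estimation of multi-exposure
imaging)** that solves for the parameters in closed order from the
semilogarithmic derivative of the contrast curve, and a spatially
regularized variant (**sREMI**) that exploits the slow spatial variation
of `β` to suppress salt-and-pepper noise. Both process entire frames as
array operations — no per-pixel iteration — at a small, quantified
accuracy cost relative to least squares.

## What is inside

- `mesi.models` — closed-form `K²(T)` for multiple-ordered
  (`g₁ = e^{-τ/τc}`, vessels), multiple-unordered (`g₁ = e^{-√(τ/τc)}`,
  parenchyma) and mixed scattering; their analytic `dK²/d ln T`; the
  critical contrast `K²(T=τc)`; boundary-ratio expansions and
  peak-amplitude polynomials used by the estimator.
- `mesi.contrast` — sliding-window (5×5/7×7) speckle contrast from raw
  frames; temporal averaging.
- `mesi.simulate` — synthetic contrast stacks with known ground truth:
  benchmark parameter grids, literature-style and log-spaced exposure
  ladders, spatial phantoms, optional ±5% uniform noise.
- `mesi.lsq` — reference bounded trust-region least squares per pixel
  (simple 3-parameter and mixed 4-parameter models), with analytic
  Jacobians.
- `mesi.remi` — the quasi-analytic pipeline: filter → differentiate →
  locate the derivative peak → extrapolate the `T→0`/`T→∞` contrast
  limits → assign the scattering model → interpolate `τc`.
- `mesi.evaluate` — log-space accuracy metrics and the full
  method × scattering-model × noise benchmark matrix.
- `mesi.io` / `mesi.cli` — float32 multi-page TIFF + JSON-sidecar I/O and
  a `remi` command-line tool (`remi fit / lsq / simulate / evaluate`).

## Worked example

Estimate flow maps for the noise-free multiple-ordered benchmark grid
(101 log-spaced flow values `1/τc ∈ [1, 10⁵] s⁻¹` × 26 dynamic-scattering
fractions `ρ ∈ [0.5, 1]`, `β = 1`) on 20 log-spaced exposures from 20 µs
to 650 ms:

```python
import numpy as np
from mesi import (SimulationGrid, exposure_set, simulate_curves,
                  remi_pipeline, logspace_r2)
from mesi.evaluate import trace_r2

grid = SimulationGrid.benchmark(d_mu=0.0)          # multiple-ordered scattering
ladder = exposure_set("logspaced", 20, 20e-6, 650e-3)
stack, truth = simulate_curves(grid, ladder)

fit = remi_pipeline(stack)                         # quasi-analytic, whole frame
est = np.where(fit.valid, fit.inv_tau_c, np.nan)

print(f"valid pixels : {fit.valid.mean():.1%}")
print(f"trace R^2    : {trace_r2(truth['inv_tau_c'], est):.4f}")
print(f"pooled R^2   : {logspace_r2(truth['inv_tau_c'], est):.4f}")
```

prints

```
valid pixels : 100.0%
trace R^2    : 0.9984
pooled R^2   : 0.9978
```

`trace R²` is the squared Pearson correlation between `log₁₀(1/τc)` and
the mean log-space estimate per true flow value (the convention of the
reference method-comparison matrix); `pooled R²` is the coefficient of
determination over all pixels, which additionally penalizes bias. A
mid-range pixel (`1/τc = 1000 s⁻¹`, `ρ = 1`) comes back as 933 s⁻¹ with
`β = 1.005`, `ρ = 1.000` — the ~7% flow deviation is the documented cost
of the quasi-analytic shortcut; `mesi.lsq.fit_mixed` recovers the same
pixel to within 0.01% at roughly a thousand times the compute.

The same comparison from the shell:

```sh
remi evaluate --methods remi-log,sremi-log,mm-lsq --n-inv-tau 21 --n-rho 6
```

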