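"""Closed-form speckle-contrast models and their semilogarithmic derivatives.

Multi-exposure speckle imaging (MESI) relates the squared speckle contrast
K²(T) recorded at exposure time T to four physical quantities:

* ``beta`` -- normalization set by speckle/pixel size mismatch and source
  coherence; the T→0 limit of K².
* ``rho`` -- fraction of detected light scattered by *moving* particles;
  sets the T→∞ floor ``beta * (1 - rho)**2``.
* ``tau_c`` -- correlation time of the scattered electric field (seconds);
  1/tau_c is the flow index.
* ``d_mu`` -- mixing weight between the multiple-ordered ("vessel",
  field autocorrelation g1 = exp(-tau/tau_c)) and multiple-unordered
  ("parenchyma", g1 = exp(-sqrt(tau/tau_c))) scattering models.

All model functions are vectorized: exposure times and parameter fields
broadcast against each other, so whole-frame evaluation is a single call.
``x = T / tau_c`` is the reduced exposure used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._empirical import boundary_coeffs, peak_poly_coeffs

__all__ = [
    "SpeckleModelParams",
    "ExposureSet",
    "k2_vessel",
    "k2_parenchyma",
    "k2_mixed",
    "k2_single",
    "k2_crit",
    "lsci_flow",
    "dk2_dlnT",
    "boundary_ratio",
    "peak_amplitude_poly",
    "BETA_MAX",
]

#: Soft upper bound on beta; noisy data may push the zero-exposure limit
#: slightly above 1, values beyond this are clamped with a warning.
BETA_MAX = 1.05

# Below this reduced exposure the rational forms suffer catastrophic
# cancellation in the (...)/x**2 terms; evaluation switches to Taylor
# series (in x for the n=1 model, in sqrt(x) for the n=0.5 model).
_SERIES_SWITCH = 1e-3


@dataclass
class SpeckleModelParams:
    """Per-pixel physical state evaluated by every model and returned by fitters.

    Fields may be scalars or arrays of a common broadcastable shape.
    """

    beta: np.ndarray | float
    rho: np.ndarray | float
    tau_c: np.ndarray | float
    d_mu: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.tau_c = np.asarray(self.tau_c, dtype=float)
        self.d_mu = np.asarray(self.d_mu, dtype=float)
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive")
        if np.any(self.beta > BETA_MAX):
            warnings.warn(
                f"beta above the soft bound {BETA_MAX} clamped", stacklevel=2
            )
            self.beta = np.minimum(self.beta, BETA_MAX)
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("rho must lie in [0, 1]")
        if np.any(self.tau_c <= 0):
            raise ValueError("tau_c must be positive")
        if np.any((self.d_mu < 0) | (self.d_mu > 1)):
            raise ValueError("d_mu must lie in [0, 1]")


@dataclass
class ExposureSet:
    """Ordered camera exposure durations (seconds) with spacing metadata.

    ``spacing`` is detected on construction: ``"log_uniform"`` when the
    ratios of consecutive exposures are constant to 1e-6 relative,
    ``"irregular"`` otherwise.
    """

    times: np.ndarray
    spacing: str = field(init=False)

    #: Relative tolerance on consecutive ratios for log-uniform detection.
    _RATIO_RTOL = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        # two exposures are enough for a container; operations that need a
        # longer ladder (filtering, fitting) enforce their own minima
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need a 1-D array of at least 2 exposure times")
        if np.any(self.times <= 0):
            raise ValueError("exposure times must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("exposure times must be strictly increasing")
        ratios = self.times[1:] / self.times[:-1]
        log_uniform = np.all(np.abs(ratios / ratios[0] - 1) < self._RATIO_RTOL)
        self.spacing = "log_uniform" if log_uniform else "irregular"

    def __len__(self) -> int:
        return self.times.size

    @property
    def ln_times(self) -> np.ndarray:
        return np.log(self.times)


def _check_T(T):
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("exposure time must be positive")
    return T


# -- reduced-exposure building blocks ---------------------------------------
# Each returns the dimensionless shape term at beta = 1; K^2 is assembled as
#   beta * (rho**2 * term1 + rho*(1-rho) * term2 + (1-rho)**2)
# where term2 already carries its 4x (vessel) / 8x (parenchyma) prefactor.


def _blend(x, direct, series, switch=_SERIES_SWITCH):
    x = np.asarray(x, dtype=float)
    small = x < switch
    safe = np.where(small, 1.0, x)
    out = direct(safe)
    if np.any(small):
        out = np.where(small, series(x), out)
    return out


def _ves_1(x):
    return _blend(
        x,
        lambda x: (np.exp(-2 * x) - 1 + 2 * x) / (2 * x**2),
        lambda x: 1 - 2 * x / 3 + x**2 / 3 - 2 * x**3 / 15 + 2 * x**4 / 45,
    )


def _ves_2(x):
    return _blend(
        x,
        lambda x: 4 * (np.exp(-x) - 1 + x) / x**2,
        lambda x: 2 - 2 * x / 3 + x**2 / 6 - x**3 / 30 + x**4 / 180,
    )


def _par_1(x):
    s = np.sqrt(np.asarray(x, dtype=float))
    return _blend(
        s,
        lambda s: (np.exp(-2 * s) * (4 * s**2 + 6 * s + 3) + 2 * s**2 - 3)
        / (2 * s**4),
        lambda s: 1 - 16 * s / 15 + 2 * s**2 / 3 - 32 * s**3 / 105 + s**4 / 9,
        switch=np.sqrt(_SERIES_SWITCH),
    )


def _par_2(x):
    s = np.sqrt(np.asarray(x, dtype=float))
    return _blend(
        s,
        lambda s: 8 * (np.exp(-s) * (2 * s**2 + 6 * s + 6) + s**2 - 6) / s**4,
        lambda s: 2 - 16 * s / 15 + s**2 / 3 - 8 * s**3 / 105 + s**4 / 72,
        switch=np.sqrt(_SERIES_SWITCH),
    )


def _dves_1(x):
    return _blend(
        x,
        lambda x: (np.exp(-2 * x) * (-x - 1) - x + 1) / x**2,
        lambda x: -2 * x / 3 + 2 * x**2 / 3 - 2 * x**3 / 5 + 8 * x**4 / 45,
    )


def _dves_2(x):
    return _blend(
        x,
        lambda x: 4 * (np.exp(-x) * (-x - 2) - x + 2) / x**2,
        lambda x: -2 * x / 3 + x**2 / 3 - x**3 / 10 + x**4 / 45,
    )


def _dpar_1(x):
    s = np.sqrt(np.asarray(x, dtype=float))
    return _blend(
        s,
        lambda s: (
            np.exp(-2 * s) * (-2 * s**3 - 5 * s**2 - 6 * s - 3) - s**2 + 3
        )
        / s**4,
        lambda s: -8 * s / 15 + 2 * s**2 / 3 - 16 * s**3 / 35 + 2 * s**4 / 9,
        switch=np.sqrt(_SERIES_SWITCH),
    )


def _dpar_2(x):
    s = np.sqrt(np.asarray(x, dtype=float))
    return _blend(
        s,
        lambda s: 8
        * (np.exp(-s) * (-s**3 - 5 * s**2 - 12 * s - 12) - s**2 + 12)
        / s**4,
        lambda s: -8 * s / 15 + s**2 / 3 - 4 * s**3 / 35 + s**4 / 36,
        switch=np.sqrt(_SERIES_SWITCH),
    )


def _assemble(x, beta, rho, t1, t2):
    return beta * (rho**2 * t1(x) + rho * (1 - rho) * t2(x) + (1 - rho) ** 2)


def k2_vessel(T, p: SpeckleModelParams):
    """Squared contrast for the multiple-ordered (vessel, n=1) model.

    K² = β [ ρ² (e^{-2x} - 1 + 2x)/(2x²) + 4ρ(1-ρ)(e^{-x} - 1 + x)/x²
             + (1-ρ)² ],  x = T/τc.
    """
    x = _check_T(T) / p.tau_c
    return _assemble(x, p.beta, p.rho, _ves_1, _ves_2)


def k2_parenchyma(T, p: SpeckleModelParams):
    """Squared contrast for the multiple-unordered (parenchyma, n=0.5) model.

    K² = β [ ρ² (e^{-2√x}(4x + 6√x + 3) + 2x - 3)/(2x²)
             + 8ρ(1-ρ)(e^{-√x}(2x + 6√x + 6) + x - 6)/x² + (1-ρ)² ].
    """
    x = _check_T(T) / p.tau_c
    return _assemble(x, p.beta, p.rho, _par_1, _par_2)


def k2_mixed(T, p: SpeckleModelParams):
    """Convex combination of the two scattering models.

    K² = (1 - d_mu) K²_vessel + d_mu K²_parenchyma; d_mu = 0 for pure
    vessel pixels, 1 for pure parenchyma.
    """
    x = _check_T(T) / p.tau_c
    ves = _assemble(x, p.beta, p.rho, _ves_1, _ves_2)
    par = _assemble(x, p.beta, p.rho, _par_1, _par_2)
    return (1 - p.d_mu) * ves + p.d_mu * par


def k2_single(T, beta, tau_c):
    """Single-parameter contrast model K² = β (e^{-2x} - 1 + 2x)/(2x²).

    Equals :func:`k2_vessel` with rho = 1 (no static scattering).
    """
    x = _check_T(T) / np.asarray(tau_c, dtype=float)
    if np.any(np.asarray(tau_c) <= 0):
        raise ValueError("tau_c must be positive")
    return np.asarray(beta, dtype=float) * _ves_1(x)


def k2_crit(p: SpeckleModelParams):
    """Contrast at the critical exposure T = τc (reduced exposure x = 1).

    Evaluated by substitution into the mixed model, which is definitionally
    the critical-contrast expression; used as the interpolation keystone
    when recovering τc.
    """
    return k2_mixed(p.tau_c, p)


def lsci_flow(K2, T, beta):
    """Single-exposure (LSCI) flow estimate 1/τc ≈ β / (T K²).

    Non-positive contrast values yield NaN rather than raising, so that
    full-frame processing continues; callers should mask non-finite output.
    """
    K2 = np.asarray(K2, dtype=float)
    T = _check_T(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.asarray(beta, dtype=float) / (T * K2)
    return np.where(K2 > 0, v, np.nan)


def dk2_dlnT(T, p: SpeckleModelParams):
    """Analytic semilogarithmic derivative dK²/d(ln T) of the mixed model.

    Non-positive everywhere for rho > 0, vanishing at both exposure
    extremes; its minimum defines T_peak, the keystone of the
    quasi-analytic estimator.
    """
    x = _check_T(T) / p.tau_c
    dves = p.beta * (
        p.rho**2 * _dves_1(x) + p.rho * (1 - p.rho) * _dves_2(x)
    )
    dpar = p.beta * (
        p.rho**2 * _dpar_1(x) + p.rho * (1 - p.rho) * _dpar_2(x)
    )
    return (1 - p.d_mu) * dves + p.d_mu * dpar


# -- empirical boundary-ratio expansions -------------------------------------


def _eval_b0(gamma, coeffs):
    c0, a1, a2, a3, a4 = coeffs
    t = np.sqrt(gamma)
    den = 1 + a1 * t + a2 * t**2 + a3 * t**3 + a4 * t**4
    return -c0 / np.sqrt(den)


def _eval_binf(gamma, coeffs):
    n1, n2, b1, b2, b3 = coeffs
    t = np.sqrt(gamma)
    den = 1 + b1 * t + b2 * t**2 + b3 * t**3 + (n2 * t**2) ** 2
    return -(n1 * t + n2 * t**2) / np.sqrt(den)


def boundary_ratio(gamma, d_mu, limit: str):
    """Empirical expansion of the slope-to-remaining-contrast ratio.

    For ``limit="zero"`` returns B0(γ) ≈ dK²/d(lnT) / (β - K²), the
    lowpass-like curve used to extrapolate K² down to its T→0 limit; for
    ``limit="inf"`` returns B∞(γ) ≈ dK²/d(lnT) / (K² - β(1-ρ)²), the
    highpass-like curve for the T→∞ limit.  γ = T/T_peak aligns the curves
    across the dynamic-scattering fraction.  Both expansions are rational
    functions of √γ under a square root (second-order filter magnitudes)
    whose coefficients are generated from the exact forward models; the
    d_mu endpoints are blended linearly, matching the mixed model.

    B0(0) = -1 (vessel) / -1/2 (parenchyma); B∞(γ→∞) → -1 for both.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    d_mu = np.asarray(d_mu, dtype=float)
    coeffs = boundary_coeffs()
    if limit == "zero":
        b_v = _eval_b0(gamma, coeffs["0"]["b0"])
        b_p = _eval_b0(gamma, coeffs["1"]["b0"])
    elif limit == "inf":
        b_v = _eval_binf(gamma, coeffs["0"]["binf"])
        b_p = _eval_binf(gamma, coeffs["1"]["binf"])
    else:
        raise ValueError("limit must be 'zero' or 'inf'")
    return (1 - d_mu) * b_v + d_mu * b_p


def peak_amplitude_poly(rho, beta=1.0):
    """Theoretical minimum of dK²/d(lnT) for both scattering models.

    Returns ``(peak_vessel, peak_parenchyma)``: the most negative
    semilogarithmic slope attainable at each dynamic-scattering fraction,
    scaled by β (a pure prefactor of the derivative).  Values come from
    degree-10 polynomials in ρ (zero constant term, since a static scene
    has a flat contrast curve) fitted to direct bounded minimization of the
    analytic derivatives; inputs are clamped to [0, 1].
    """
    rho = np.clip(np.asarray(rho, dtype=float), 0.0, 1.0)
    beta = np.asarray(beta, dtype=float)
    c0, c1 = peak_poly_coeffs()
    # polynomials through the origin: coeffs are for rho^1 .. rho^10
    p0 = _poly_origin(rho, c0)
    p1 = _poly_origin(rho, c1)
    return beta * p0, beta * p1


def _poly_origin(rho, coeffs):
    """Evaluate sum_k coeffs[k] * rho**(k+1) (Horner, no constant term)."""
    acc = np.zeros_like(rho)
    for c in coeffs[::-1]:
        acc = (acc + c) * rho
    return acc
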