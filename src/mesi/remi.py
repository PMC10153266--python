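"""The quasi-analytic multi-exposure estimator (REMI) and its spatially
regularized variant (sREMI).

Instead of iterating a nonlinear solver per pixel, the estimator solves
for the unknowns in a fixed order using limiting properties of the mixed
scattering model:

1.  filter K²(T) along the exposure axis and differentiate with respect
    to ln T;
2.  locate the derivative minimum T_peak by quadratic interpolation —
    T_peak sits within roughly 0.8-3.3x the true correlation time;
3.  extrapolate the shortest/longest-exposure samples to the T→0 and T→∞
    limits of K² through the boundary-ratio expansions B0 and B∞
    (γ = T/T_peak), giving β = lim_{T→0} K² and, through
    ρ = 1 − sqrt(lim_∞/lim_0), the dynamic-scattering fraction;
4.  assign the scattering-model weight d_mu by comparing the measured
    peak amplitude with the theoretical minima of the two models;
5.  (sREMI) spatially smooth the β map — β varies slowly across a field
    of view — and repeat the d_mu assignment with the smoothed β;
6.  compute the critical contrast K²_crit = K²(T = τc) from the final
    parameters and recover τc by log-linear interpolation of the
    contrast curve through it.

Correlation times outside the exposure-supported window cannot be
resolved; the estimator is built so that such pixels saturate smoothly
(the derivative-peak location and the recovered τc are both confined to
one decade beyond the ladder) instead of diverging.

Every stage operates on whole (n_exposures, H, W) arrays; there is no
per-pixel Python iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contrast import ContrastStack
from .lsq import FitResult
from .models import (
    BETA_MAX,
    SpeckleModelParams,
    boundary_ratio,
    k2_crit,
    peak_amplitude_poly,
)

__all__ = [
    "DerivativeCurve",
    "RemiState",
    "prefilter",
    "semilog_derivative",
    "locate_peak",
    "estimate_limits",
    "assign_dmu",
    "smooth_beta",
    "interpolate_tau",
    "remi_pipeline",
]

#: Multiplicative compensation for moving-average attenuation of the
#: derivative; each derivative sample entering the model assignment or
#: the limit extrapolation is compensated exactly once.
PEAK_COMPENSATION = 1.05
#: |dK²| below this fraction of the pixel's maximum contrast flags the
#: pixel as static (flat curve, rho -> 0 path).
STATIC_EPS = 1e-6
#: Estimated rho below which the beta/2 cap on the critical contrast is
#: applied (guards against falsely high flow at near-zero slope).
RHO_CAP_THRESHOLD = 0.2
#: How far beyond the sampled ln T range the derivative-peak vertex and
#: the recovered correlation time may extrapolate (decades).
SATURATION_DECADES = 1.0

_LN10 = np.log(10.0)


@dataclass
class DerivativeCurve:
    """Filtered dK²/d(ln T) samples at positions centered between exposures.

    ``k2`` holds the (filtered) contrast resampled onto the same centered
    positions, so that each derivative sample has an aligned contrast
    sample for the boundary extrapolations.
    """

    ln_t: np.ndarray  # (m,) strictly increasing, m = n_exposures - 1
    dk2: np.ndarray  # (m, H, W)
    k2: np.ndarray  # (m, H, W) contrast aligned to ln_t

    @property
    def t(self) -> np.ndarray:
        return np.exp(self.ln_t)


@dataclass
class RemiState:
    """Intermediate per-pixel quantities of the estimator (diagnostics)."""

    t_peak: np.ndarray
    dk2_peak: np.ndarray  # after attenuation compensation
    k2_lim0: np.ndarray  # beta estimate
    k2_liminf: np.ndarray  # beta (1 - rho)^2 estimate
    rho: np.ndarray
    d_mu: np.ndarray
    k2_crit: np.ndarray
    static: np.ndarray


def _local_linear_weights(ln_pos: np.ndarray, half_width: float) -> np.ndarray:
    """Equivalent-kernel matrix of a weighted local-linear smoother.

    Row i holds the weights that evaluate a weighted straight-line fit
    (in ln T) at position i, with inverse-distance weights
    1/(|Δln T| + half_width/4) inside a ±``half_width`` window.  Unlike a
    plain weighted moving average, the local-linear form reproduces
    straight lines exactly and therefore has no first-order bias at the
    ladder ends, where the window is one-sided.  This is the stand-in
    for the nonuniform moving-average filter of irregular ladders.
    """
    d = ln_pos[:, None] - ln_pos[None, :]
    ad = np.abs(d)
    w = np.where(ad <= half_width, 1.0 / (ad + half_width / 4), 0.0)
    s0 = w.sum(axis=1, keepdims=True)
    s1 = (w * d).sum(axis=1, keepdims=True)
    s2 = (w * d * d).sum(axis=1, keepdims=True)
    den = s0 * s2 - s1 * s1
    flat = np.abs(den) < 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        out = w * (s2 - s1 * d) / den
    return np.where(flat, w / s0, out)


def prefilter(stack: ContrastStack) -> ContrastStack:
    """First-stage smoothing of K² along the exposure axis.

    Log-uniform ladders use the 1:4:1 weighted moving average (replicate
    padding at the ends); irregular ladders use the weighted local-linear
    smoother within a ±1/3-decade window.
    """
    if len(stack.exposure_set) < 5:
        raise ValueError("need at least 5 exposures to filter and differentiate")
    k2 = stack.k2
    if stack.exposure_set.spacing == "log_uniform":
        padded = np.concatenate([k2[:1], k2, k2[-1:]], axis=0)
        out = (padded[:-2] + 4 * padded[1:-1] + padded[2:]) / 6.0
    else:
        w = _local_linear_weights(stack.exposure_set.ln_times, _LN10 / 3)
        out = np.clip(np.tensordot(w, k2, axes=(1, 0)), 0.0, None)
    return ContrastStack(out, stack.exposure_set, stack.valid)


def semilog_derivative(filtered: ContrastStack) -> DerivativeCurve:
    """Centered differences of K² over ln T, with second-stage smoothing.

    Differences are taken between consecutive exposures and attributed to
    the midpoint in ln T.  The derivative is then smoothed again: a
    3-point moving average for log-uniform ladders, a local-linear
    weighted average of one-decade width for irregular ones.  The
    contrast itself is resampled onto the midpoint positions (linear in
    ln T, equivalently using the centered differential to interpolate).
    """
    ln_T = filtered.exposure_set.ln_times
    k2 = filtered.k2
    dln = np.diff(ln_T)[:, None, None]
    dk2 = np.diff(k2, axis=0) / dln
    mid = (ln_T[:-1] + ln_T[1:]) / 2
    k2_mid = (k2[:-1] + k2[1:]) / 2  # midpoints in ln T -> linear interp
    if filtered.exposure_set.spacing == "log_uniform":
        padded = np.concatenate([dk2[:1], dk2, dk2[-1:]], axis=0)
        dk2s = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    else:
        w = _local_linear_weights(mid, _LN10 / 2)
        dk2s = np.tensordot(w, dk2, axes=(1, 0))
    return DerivativeCurve(ln_t=mid, dk2=dk2s, k2=k2_mid)


def locate_peak(curve: DerivativeCurve):
    """Derivative-minimum location and amplitude by quadratic interpolation.

    The minimum sample and its two neighbors define a quadratic Newton
    interpolation polynomial; its vertex gives T_peak and the polynomial
    value there — raised by the 5% attenuation compensation — gives the
    peak amplitude.  The vertex may extrapolate up to one decade beyond
    the sampled range: when the minimum sits at a ladder end and the
    local quadratic is degenerate or concave (the true peak lies outside
    the ladder), the peak is placed one decade past that end with the
    sampled minimum as its amplitude, so out-of-range pixels saturate
    instead of diverging.

    Returns ``(t_peak, dk2_peak, static)``; pixels whose derivative never
    drops below ``-STATIC_EPS * max K²`` are flagged static.
    """
    dk2, ln_t = curve.dk2, curve.ln_t
    m = dk2.shape[0]
    if m < 3:
        raise ValueError("need at least 3 derivative samples")
    lo, hi = ln_t[0] - SATURATION_DECADES * _LN10, ln_t[-1] + SATURATION_DECADES * _LN10
    i_min = np.argmin(dk2, axis=0)
    j = np.clip(i_min, 1, m - 2)
    l0, l1, l2 = ln_t[j - 1], ln_t[j], ln_t[j + 1]
    take = np.take_along_axis
    d0 = take(dk2, (j - 1)[None], axis=0)[0]
    d1 = take(dk2, j[None], axis=0)[0]
    d2 = take(dk2, (j + 1)[None], axis=0)[0]
    d_min = take(dk2, i_min[None], axis=0)[0]
    f01 = (d1 - d0) / (l1 - l0)
    f12 = (d2 - d1) / (l2 - l1)
    f012 = (f12 - f01) / (l2 - l0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = 0.5 * (l0 + l1) - f01 / (2 * f012)
    # concave or degenerate quadratic: no interior minimum exists
    concave = ~np.isfinite(vertex) | (f012 <= 0)
    edge_fallback = np.where(i_min == m - 1, hi, np.where(i_min == 0, lo, l1))
    vertex = np.where(concave, edge_fallback, vertex)
    vertex = np.clip(vertex, lo, hi)
    amp = d0 + f01 * (vertex - l0) + f012 * (vertex - l0) * (vertex - l1)
    # the interpolated peak can only deepen the sampled minimum
    amp = np.where(concave, d_min, np.minimum(amp, d_min))
    static = dk2.min(axis=0) >= -STATIC_EPS * curve.k2.max(axis=0)
    return np.exp(vertex), PEAK_COMPENSATION * amp, static


def estimate_limits(curve: DerivativeCurve, t_peak, d_mu):
    """Extrapolate the ladder ends to the T→0 and T→∞ contrast limits.

    β = K²(T_first) + dK²(T_first)/B0(T_first/T_peak) and
    β(1−ρ)² = K²(T_last) − dK²(T_last)/B∞(T_last/T_peak), with the
    derivative samples compensated for filter attenuation.  The long-
    exposure limit is clamped to [0, lim0] and ρ follows from
    ρ = 1 − sqrt(lim∞ / lim0).
    """
    t_first, t_last = curve.t[0], curve.t[-1]
    k2_first, k2_last = curve.k2[0], curve.k2[-1]
    dk2_first = PEAK_COMPENSATION * curve.dk2[0]
    dk2_last = PEAK_COMPENSATION * curve.dk2[-1]
    b0 = boundary_ratio(t_first / t_peak, d_mu, "zero")
    binf = boundary_ratio(t_last / t_peak, d_mu, "inf")
    # B0 is bounded away from 0 by construction; B_inf vanishes as the
    # peak moves past the ladder end -- guard the division
    lim0 = k2_first + dk2_first / b0
    small = np.abs(binf) < 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        liminf = np.where(small, k2_last, k2_last - dk2_last / binf)
    lim0 = np.maximum(lim0, 1e-9)
    liminf = np.clip(liminf, 0.0, lim0)
    rho = np.clip(1 - np.sqrt(liminf / lim0), 0.0, 1.0)
    return lim0, liminf, rho


def assign_dmu(dk2_peak, rho, beta):
    """Scattering-model weight from the measured peak amplitude.

    The distance of the (compensated) derivative minimum from the
    theoretical vessel-model peak, normalized by the distance between the
    vessel and parenchyma theoretical peaks, clamped to [0, 1].  Pixels
    with indistinguishable peaks (rho ≈ 0) get d_mu = 0.
    """
    p0, p1 = peak_amplitude_poly(rho, beta)
    denom = p1 - p0
    degenerate = np.abs(denom) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (np.asarray(dk2_peak) - p0) / denom
    return np.clip(np.where(degenerate, 0.0, d), 0.0, 1.0)


def smooth_beta(beta_map, sigma: float | None = None, size: float | None = None):
    """Spatial Gaussian smoothing of the β map (sREMI).

    β varies slowly across a field of view (aberrations, defocus), so a
    wide kernel suppresses per-pixel salt-and-pepper noise.  Defaults:
    kernel size 10% of the smaller image dimension with σ = size/2, i.e.
    the Gaussian is truncated at one σ; borders are reflective.
    """
    beta_map = np.asarray(beta_map, dtype=float)
    if beta_map.ndim != 2:
        raise ValueError("beta map must be 2-D")
    if sigma is None:
        sigma = (size / 2) if size is not None else 0.05 * min(beta_map.shape)
    truncate = (size / (2 * sigma)) if size is not None else 1.0
    return ndimage.gaussian_filter(beta_map, sigma, mode="reflect", truncate=truncate)


def interpolate_tau(filtered: ContrastStack, kcrit):
    """Recover τc from the crossing of K²(T) through the critical contrast.

    For each pixel, ``idx`` is the last exposure with K² above K²_crit;
    log τc is linearly interpolated between exposures idx and idx+1:

        log τc = (K²_crit − K²_idx) (log T_idx+1 − log T_idx)
                 / (K²_idx+1 − K²_idx) + log T_idx

    If every sample stays above K²_crit the last two exposures
    extrapolate; if the first sample is already below, the first two do.
    Pixels with a degenerate bracket (equal contrasts) come back NaN.
    """
    k2 = filtered.k2
    n = k2.shape[0]
    log_T = np.log10(filtered.exposure_set.times)
    above = k2 > np.asarray(kcrit)[None]
    any_above = above.any(axis=0)
    last_above = (n - 1) - np.argmax(above[::-1], axis=0)
    idx = np.where(any_above, np.minimum(last_above, n - 2), 0)
    take = np.take_along_axis
    k_a = take(k2, idx[None], axis=0)[0]
    k_b = take(k2, (idx + 1)[None], axis=0)[0]
    t_a = log_T[idx]
    t_b = log_T[idx + 1]
    dk = k_b - k_a
    with np.errstate(divide="ignore", invalid="ignore"):
        log_tau = (np.asarray(kcrit) - k_a) * (t_b - t_a) / dk + t_a
    log_tau = np.where(dk == 0, np.nan, log_tau)
    return 10.0**log_tau


def remi_pipeline(
    stack: ContrastStack,
    spatial: bool = False,
    sigma: float | None = None,
    size: float | None = None,
) -> FitResult:
    """Full quasi-analytic estimation of (β, ρ, τc, d_mu) maps.

    ``spatial=True`` enables the sREMI β-smoothing stage (with ``spatial=
    False`` the output is identical to plain REMI).  All stages are
    array-wide; per-pixel failures are flagged in the validity mask, never
    raised.  Recovered correlation times are confined to one decade
    beyond the exposure ladder — values at those rails mean "outside the
    supported range", not a resolved measurement.
    """
    filt = prefilter(stack)
    curve = semilog_derivative(filt)
    t_peak, dk2_peak, static = locate_peak(curve)

    # first pass under the vessel model assumption
    lim0_0, liminf_0, rho_0 = estimate_limits(curve, t_peak, d_mu=0.0)
    d_mu = assign_dmu(dk2_peak, rho_0, lim0_0)

    if spatial:
        lim0_1, _, _ = estimate_limits(curve, t_peak, d_mu)
        beta = smooth_beta(lim0_1, sigma=sigma, size=size)
        # repeat the model assignment with the smoothed zero-exposure limit
        rho_s = np.clip(1 - np.sqrt(np.clip(liminf_0 / beta, 0.0, 1.0)), 0.0, 1.0)
        d_mu = assign_dmu(dk2_peak, rho_s, beta)
    else:
        beta, _, _ = estimate_limits(curve, t_peak, d_mu)

    # final long-exposure limit and rho with the assigned model weight
    _, liminf, _ = estimate_limits(curve, t_peak, d_mu)
    liminf = np.clip(liminf, 0.0, beta)
    rho = np.clip(1 - np.sqrt(liminf / beta), 0.0, 1.0)

    rho_fit = np.where(static, 0.0, rho)
    d_mu = np.where(static, 0.0, d_mu)
    beta_fit = np.clip(beta, 1e-9, BETA_MAX)  # soft bound, documented
    params = SpeckleModelParams(
        beta=beta_fit,
        rho=rho_fit,
        tau_c=np.where(np.isfinite(t_peak), t_peak, 1.0),
        d_mu=d_mu,
    )
    kcrit = k2_crit(params)
    cap = rho_fit < RHO_CAP_THRESHOLD
    kcrit = np.where(cap, np.minimum(kcrit, beta_fit / 2), kcrit)

    tau = interpolate_tau(filt, kcrit)
    T = stack.exposure_set.times
    sat = 10.0**SATURATION_DECADES
    tau = np.clip(tau, T[0] / sat, T[-1] * sat)
    tau = np.where(static, np.nan, tau)
    valid = (
        np.asarray(stack.valid, dtype=bool)
        & ~static
        & np.isfinite(tau)
        & (tau > 0)
    )
    state = RemiState(
        t_peak=t_peak,
        dk2_peak=dk2_peak,
        k2_lim0=np.asarray(beta),
        k2_liminf=liminf,
        rho=rho_fit,
        d_mu=d_mu,
        k2_crit=kcrit,
        static=static,
    )
    zeros = np.zeros_like(np.asarray(beta_fit))
    return FitResult(
        beta=beta_fit,
        rho=rho_fit,
        tau_c=tau,
        d_mu=d_mu,
        rss=np.full_like(zeros, np.nan),
        converged=~static,
        n_iter=zeros.astype(int),
        valid=valid,
        diagnostics={
            "method": "sremi" if spatial else "remi",
            "state": state,
        },
    )
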