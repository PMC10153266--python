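"""Reference per-pixel nonlinear least-squares fitting of the contrast models.

This is the conventional (slow) MESI analysis: bounded trust-region
least squares of K²(T) per pixel, either to the simple vessel model
(three parameters: beta, rho, tau_c) or to the mixed scattering model
(adding d_mu).  It serves as the accuracy reference the quasi-analytic
estimator is judged against.

Fits run in K² space with tau_c optimized as log10(tau_c) for
conditioning.  Initialization is data-driven (see ``_initial_guess``)
with two deterministic restarts perturbing the initial correlation time
by one decade either way; restarts are skipped once a start has reached
a numerically negligible residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .contrast import ContrastStack
from .models import (  # reduced-exposure shape terms for fast evaluation
    BETA_MAX,
    SpeckleModelParams,
    _dpar_1,
    _dpar_2,
    _dves_1,
    _dves_2,
    _par_1,
    _par_2,
    _ves_1,
    _ves_2,
)

__all__ = ["FitResult", "fit_simple", "fit_mixed"]

_LOG_TAU_BOUNDS = (-8.0, 2.0)  # tau_c in [1e-8, 1e2] s
_FTOL = 1e-10
_MAX_ITER = 200
#: residual sum of squares (squared-contrast units) below which a start is
#: considered at the global optimum and the remaining restarts are skipped;
#: far below the residual floor of any noisy curve
_RSS_SKIP = 1e-9


@dataclass
class FitResult:
    """Per-pixel parameter maps plus fit diagnostics."""

    beta: np.ndarray
    rho: np.ndarray
    tau_c: np.ndarray
    d_mu: np.ndarray | None
    rss: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    valid: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def inv_tau_c(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.tau_c

    def params(self) -> SpeckleModelParams:
        d_mu = self.d_mu if self.d_mu is not None else 0.0
        return SpeckleModelParams(self.beta, self.rho, self.tau_c, d_mu)


_LN10 = np.log(10.0)


class _PixelModel:
    """Model curve and analytic Jacobian for one pixel, evaluated together.

    The optimizer requests the residual and the Jacobian at the same
    point back to back; both are assembled from one evaluation of the
    reduced-exposure shape terms and cached on the parameter vector.

    Parameters are (beta, rho, log10 tau_c[, d_mu]).  beta and d_mu
    enter linearly; the rho partial follows from the quadratic parameter
    structure; the log-tau partial is the negated semilogarithmic
    derivative (tau_c enters x = T/tau_c only through -ln tau_c).
    """

    def __init__(self, T, k2, mixed):
        self.T = T
        self.k2 = k2
        self.mixed = mixed
        self._key = None

    def _eval(self, theta):
        key = tuple(theta)
        if key == self._key:
            return self._cache
        beta, rho, log_tau = theta[:3]
        d_mu = theta[3] if self.mixed else 0.0
        x = self.T / 10.0**log_tau
        v1, v2 = _ves_1(x), _ves_2(x)
        ves = rho**2 * v1 + rho * (1 - rho) * v2 + (1 - rho) ** 2
        dves_rho = 2 * rho * v1 + (1 - 2 * rho) * v2 - 2 * (1 - rho)
        dves_ln = rho**2 * _dves_1(x) + rho * (1 - rho) * _dves_2(x)
        if self.mixed:
            p1, p2 = _par_1(x), _par_2(x)
            par = rho**2 * p1 + rho * (1 - rho) * p2 + (1 - rho) ** 2
            dpar_rho = 2 * rho * p1 + (1 - 2 * rho) * p2 - 2 * (1 - rho)
            dpar_ln = rho**2 * _dpar_1(x) + rho * (1 - rho) * _dpar_2(x)
        else:
            par, dpar_rho, dpar_ln = ves, dves_rho, dves_ln
        shape = (1 - d_mu) * ves + d_mu * par
        cols = [
            shape,
            beta * ((1 - d_mu) * dves_rho + d_mu * dpar_rho),
            -_LN10 * beta * ((1 - d_mu) * dves_ln + d_mu * dpar_ln),
        ]
        if self.mixed:
            cols.append(beta * (par - ves))
        self._key = key
        self._cache = (beta * shape, np.stack(cols, axis=1))
        return self._cache

    def fun(self, theta):
        return self._eval(theta)[0] - self.k2

    def jac(self, theta):
        return self._eval(theta)[1]


def _model_curve(theta, T, mixed):
    """Model curve at a parameter vector (used by tests and diagnostics)."""
    return _PixelModel(T, np.zeros_like(T), mixed).fun(theta)


def _initial_guess(k2, T):
    """Cheap physical initialization from the curve itself.

    beta0 = max K² (short-exposure end), rho0 from the contrast drop via
    rho = 1 - sqrt(K²_min / K²_max), tau_c0 from the single-exposure flow
    estimate beta/(T K²) at the mid-ladder exposure.
    """
    beta0 = float(np.clip(k2.max(), 1e-3, BETA_MAX))
    ratio = float(np.clip(k2.min() / max(k2.max(), 1e-12), 0.0, 1.0))
    rho0 = float(np.clip(1 - np.sqrt(ratio), 0.05, 1.0))
    mid = len(T) // 2
    inv_tau0 = beta0 / (T[mid] * max(k2[mid], 1e-9))
    log_tau0 = float(np.clip(-np.log10(inv_tau0), *_LOG_TAU_BOUNDS))
    return beta0, rho0, log_tau0


def _fit_pixel(k2, T, mixed):
    beta0, rho0, log_tau0 = _initial_guess(k2, T)
    lo = [1e-6, 0.0, _LOG_TAU_BOUNDS[0]]
    hi = [BETA_MAX, 1.0, _LOG_TAU_BOUNDS[1]]
    starts = []
    for dlog in (0.0, 1.0, -1.0):
        t0 = float(np.clip(log_tau0 + dlog, *_LOG_TAU_BOUNDS))
        theta0 = [beta0, rho0, t0] + ([0.5] if mixed else [])
        starts.append(np.asarray(theta0))
    if mixed:
        lo, hi = lo + [0.0], hi + [1.0]
    lo, hi = np.asarray(lo), np.asarray(hi)

    best = None
    model = _PixelModel(T, k2, mixed)
    for theta0 in starts:
        res = least_squares(
            model.fun,
            np.clip(theta0, lo + 1e-12, hi - 1e-12),
            jac=model.jac,
            bounds=(lo, hi),
            method="trf",
            ftol=_FTOL,
            xtol=1e-12,
            max_nfev=_MAX_ITER,
        )
        rss = float(2 * res.cost)
        if best is None or rss < best[1]:
            best = (res, rss)
        if rss < _RSS_SKIP:
            break
    res, rss = best
    return res.x, rss, bool(res.status > 0), int(res.nfev)


def _fit_stack(stack: ContrastStack, mixed: bool, min_exposures: int) -> FitResult:
    n_exp, h, w = stack.k2.shape
    if n_exp < min_exposures:
        raise ValueError(
            f"need at least {min_exposures} exposures for this model"
        )
    T = stack.exposure_set.times
    n_par = 4 if mixed else 3
    theta = np.full((h, w, n_par), np.nan)
    rss = np.full((h, w), np.nan)
    converged = np.zeros((h, w), dtype=bool)
    n_iter = np.zeros((h, w), dtype=int)
    valid = np.array(stack.valid, dtype=bool, copy=True)
    flat_threshold = 1e-6

    for i in range(h):
        for j in range(w):
            if not valid[i, j]:
                continue
            k2 = stack.k2[:, i, j]
            if not np.all(np.isfinite(k2)):
                valid[i, j] = False
                continue
            if k2.max() - k2.min() < flat_threshold * max(k2.max(), 1e-12):
                # flat curve: no dynamic scattering, tau_c unidentifiable
                theta[i, j] = [k2.mean(), 0.0, np.nan] + ([0.0] if mixed else [])
                rss[i, j] = 0.0
                valid[i, j] = False
                continue
            th, r, conv, nit = _fit_pixel(k2, T, mixed)
            theta[i, j, :] = th
            rss[i, j] = r
            converged[i, j] = conv
            n_iter[i, j] = nit
            valid[i, j] &= conv

    tau = np.where(np.isfinite(theta[..., 2]), 10.0 ** theta[..., 2], np.nan)
    return FitResult(
        beta=theta[..., 0],
        rho=theta[..., 1],
        tau_c=tau,
        d_mu=theta[..., 3] if mixed else None,
        rss=rss,
        converged=converged,
        n_iter=n_iter,
        valid=valid,
        diagnostics={"model": "mixed" if mixed else "simple"},
    )


def fit_simple(stack: ContrastStack) -> FitResult:
    """Per-pixel bounded least squares of the vessel (n=1) model.

    Three free parameters (beta, rho, tau_c); requires >= 4 exposures.
    """
    return _fit_stack(stack, mixed=False, min_exposures=4)


def fit_mixed(stack: ContrastStack) -> FitResult:
    """Per-pixel bounded least squares of the mixed scattering model.

    Four free parameters (beta, rho, tau_c, d_mu with d_mu free in
    [0, 1]); requires >= 5 exposures.
    """
    return _fit_stack(stack, mixed=True, min_exposures=5)
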