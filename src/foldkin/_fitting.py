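"""Shared nonlinear least-squares machinery.

A thin multi-start wrapper around :func:`scipy.optimize.curve_fit`:
the physically motivated initial guess is tried first, then jittered
restarts (+-20% uniform) before a fit is declared failed. Fits are
unweighted unless per-point sigmas are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import FitFailureError

logger = logging.getLogger("foldkin")

N_STARTS = 5
JITTER = 0.20


@dataclass
class CurveFitOutcome:
    popt: np.ndarray
    pcov: np.ndarray
    perr: np.ndarray
    residual_norm: float
    n_points: int
    n_params: int

    @property
    def dof(self) -> int:
        return max(self.n_points - self.n_params, 1)


def _try_fit(model, x, y, p0, sigma, bounds, maxfev):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=p0,
            sigma=sigma,
            bounds=bounds,
            maxfev=maxfev,
            absolute_sigma=sigma is not None,
        )
    resid = y - model(x, *popt)
    return popt, pcov, float(np.sqrt(np.sum(resid**2)))


def multistart_curve_fit(
    model,
    x: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray,
    *,
    sigma: np.ndarray | None = None,
    bounds=(-np.inf, np.inf),
    n_starts: int = N_STARTS,
    jitter: float = JITTER,
    maxfev: int = 20000,
    seed: int = 0,
    label: str = "fit",
) -> CurveFitOutcome:
    """Fit ``model`` to (x, y), restarting from jittered guesses on failure.

    Raises :class:`FitFailureError` carrying the best residual norm seen
    if no start converges.
    """
    p0 = np.asarray(p0, dtype=float)
    logger.info("%s: initial guess %s", label, np.array2string(p0, precision=4))
    rng = np.random.default_rng(seed)
    best = None
    best_resid = None
    lo, hi = bounds
    # an essentially perfect fit (noise-free data) ends the search early;
    # otherwise all starts run and the lowest residual wins
    perfect = 1e-9 * max(1.0, float(np.linalg.norm(y)))
    for start in range(n_starts):
        if start == 0:
            guess = p0
        else:
            guess = p0 * (1.0 + jitter * rng.uniform(-1, 1, size=p0.shape))
            guess = np.clip(guess, lo, hi)
        logger.debug("%s: start %d from %s", label, start, guess)
        try:
            popt, pcov, resid = _try_fit(model, x, y, guess, sigma, bounds, maxfev)
        except (RuntimeError, ValueError) as exc:
            logger.debug("%s: start %d failed (%s)", label, start, exc)
            continue
        if not np.all(np.isfinite(popt)):
            continue
        if best_resid is None or resid < best_resid:
            best, best_resid = (popt, pcov), resid
        if best_resid < perfect:
            break
    if best is None:
        raise FitFailureError(
            f"{label}: no convergence after {n_starts} starts", best_residual=best_resid
        )
    popt, pcov = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    logger.info(
        "%s: converged, residual norm %.4g, params %s",
        label,
        best_resid,
        np.array2string(popt, precision=5),
    )
    return CurveFitOutcome(
        popt=popt,
        pcov=pcov,
        perr=perr,
        residual_norm=best_resid,
        n_points=len(np.asarray(x)),
        n_params=len(p0),
    )


def smooth5(y: np.ndarray) -> np.ndarray:
    """5-point moving average with edge padding (for guess heuristics)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        return y.copy()
    padded = np.concatenate([y[:2][::-1], y, y[-2:][::-1]])
    kernel = np.ones(5) / 5.0
    return np.convolve(padded, kernel, mode="valid")


def aic_from_rss(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC from a residual sum of squares."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def edge_baseline_guess(p: np.ndarray, s: np.ndarray, frac: float = 0.2):
    """Linear fits to the outer ``frac`` of points at each end.

    Returns (alpha_N, beta_N, alpha_D, beta_D) assuming the native state
    dominates at low perturbation.
    """
    n = len(p)
    k = max(2, int(np.ceil(frac * n)))
    bN, aN = np.polyfit(p[:k], s[:k], 1)
    bD, aD = np.polyfit(p[-k:], s[-k:], 1)
    return aN, bN, aD, bD
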