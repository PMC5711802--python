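"""Two-state equilibrium denaturation analysis.

The observable signal of a two-state folder under a perturbation P
(denaturant concentration or temperature) is the population-weighted
average of two linearly sloping baselines:

    S(P) = [a_N + b_N*P + (a_D + b_D*P) * exp(-dG(P)/RT)]
           / [1 + exp(-dG(P)/RT)]

Chemical denaturation uses the linear free-energy relationship
dG(u) = dG0 - m*u = m*(u50 - u); thermal denaturation uses the
Gibbs-Helmholtz expression around the midpoint T_m with a fixed heat
capacity increment dCp. Free energies are in kcal/mol throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._fitting import (
    aic_from_rss,
    edge_baseline_guess,
    multistart_curve_fit,
    smooth5,
)
from ._results import FitResultBase
from .constants import DEFAULT_CONSTANTS, Constants
from .datasets import DenaturationCurve, DenaturationMode
from .exceptions import (
    DegenerateNormalizationError,
    FitFailureError,
    InvalidInputError,
    NumericalError,
)

__all__ = [
    "two_state_signal",
    "lfer_dG",
    "gibbs_helmholtz_dG",
    "ChemicalFitResult",
    "ThermalFitResult",
    "ChemicalDenaturationModel",
    "ThermalDenaturationModel",
    "fit_chemical_denaturation",
    "fit_thermal_denaturation",
    "dG_from_m_and_midpoint",
    "propagate_dG_error",
    "schellman_ddG",
    "folded_fraction",
]

# 10-90% transition width relates to the free-energy slope through
# dG/RT = +-ln(9) at the edges of the transition zone.
_LN81 = 2.0 * math.log(9.0)


def two_state_signal(P, dG_fn, baselines, T, *, R=DEFAULT_CONSTANTS.R):
    """Two-state observable at perturbation ``P``.

    Parameters
    ----------
    P : float or ndarray
        Perturbation value(s) (urea in M or temperature in K).
    dG_fn : callable or float or ndarray
        Unfolding free energy dG(P) in kcal/mol, either as a function of
        P or already evaluated.
    baselines : tuple
        (alpha_N, beta_N, alpha_D, beta_D).
    T : float or ndarray
        Temperature (K) at which the Boltzmann factor is evaluated.

    Evaluated through the logistic function of dG/RT, so it is stable
    for arbitrarily large |dG|/RT.
    """
    P = np.asarray(P, dtype=float)
    dG = dG_fn(P) if callable(dG_fn) else np.asarray(dG_fn, dtype=float)
    if not np.all(np.isfinite(dG)):
        raise InvalidInputError("dG(P) is non-finite")
    if np.any(np.asarray(T, dtype=float) <= 0):
        raise InvalidInputError("temperature must be positive")
    aN, bN, aD, bD = baselines
    f_N = expit(dG / (R * np.asarray(T, dtype=float)))  # native population
    return f_N * (aN + bN * P) + (1.0 - f_N) * (aD + bD * P)


def lfer_dG(urea, m_DN, urea50):
    """Linear free-energy relationship: dG(u) = m * (u50 - u)."""
    return m_DN * (urea50 - np.asarray(urea, dtype=float))


def gibbs_helmholtz_dG(T, dH_m, T_m, dCp):
    """Gibbs-Helmholtz unfolding free energy around the melt midpoint.

    dG(T) = dH_m (1 - T/T_m) - dCp [T_m - T + T ln(T/T_m)]; zero at T_m
    for any dCp.
    """
    T = np.asarray(T, dtype=float)
    return dH_m * (1.0 - T / T_m) - dCp * (T_m - T + T * np.log(T / T_m))


def dG_from_m_and_midpoint(m_DN: float, urea50: float) -> float:
    """Unfolding free energy in water, dG = m * [urea]_50."""
    if not (np.isfinite(m_DN) and np.isfinite(urea50)):
        raise InvalidInputError("arguments must be finite")
    return m_DN * urea50


def propagate_dG_error(
    m: float, sigma_m: float, urea50: float, sigma_mid: float, cov_m_mid: float = 0.0
) -> float:
    """Propagated standard error of dG = m * u50.

    sigma^2 = (u50*s_m)^2 + (m*s_mid)^2 + 2*m*u50*cov(m, u50); with the
    covariance omitted this is the independent-error form.
    """
    if sigma_m < 0 or sigma_mid < 0:
        raise InvalidInputError("standard errors must be non-negative")
    var = (urea50 * sigma_m) ** 2 + (m * sigma_mid) ** 2 + 2.0 * m * urea50 * cov_m_mid
    if var < 0:
        raise NumericalError("negative variance after covariance term")
    return math.sqrt(var)


def schellman_ddG(dH_m: float, T_m: float, dT_m: float) -> float:
    """Stability change from a midpoint-temperature shift.

    ddG = (dH_m / T_m) * dT_m, assuming midpoint entropy is conserved.
    """
    if T_m <= 0:
        raise InvalidInputError("T_m must be positive")
    return dH_m / T_m * dT_m


# ---------------------------------------------------------------------------
# Chemical denaturation
# ---------------------------------------------------------------------------

_CHEM_PARAMS = ["m_DN", "urea50", "alpha_N", "beta_N", "alpha_D", "beta_D"]


@dataclass
class ChemicalFitResult(FitResultBase):
    """Fitted two-state chemical denaturation curve.

    ``dG_DN = m_DN * urea50`` by construction; ``dG_DN_err`` includes the
    fitted m/midpoint covariance, ``dG_DN_err_independent`` does not.
    """

    temperature: float = DEFAULT_CONSTANTS.T_ref
    curve: DenaturationCurve | None = field(default=None, repr=False)

    @property
    def m_DN(self) -> float:
        return float(self.popt[0])

    @property
    def urea50(self) -> float:
        return float(self.popt[1])

    @property
    def baselines(self) -> tuple[float, float, float, float]:
        return tuple(float(v) for v in self.popt[2:6])

    @property
    def dG_DN(self) -> float:
        return dG_from_m_and_midpoint(self.m_DN, self.urea50)

    @property
    def dG_DN_err(self) -> float:
        b = self.bse
        return propagate_dG_error(
            self.m_DN, b["m_DN"], self.urea50, b["urea50"], self.pcov[0, 1]
        )

    @property
    def dG_DN_err_independent(self) -> float:
        b = self.bse
        return propagate_dG_error(self.m_DN, b["m_DN"], self.urea50, b["urea50"])

    def predict(self, urea) -> np.ndarray:
        return two_state_signal(
            urea,
            lambda u: lfer_dG(u, self.m_DN, self.urea50),
            self.baselines,
            self.temperature,
        )

    def _derived_rows(self):
        return [("dG_DN", self.dG_DN, self.dG_DN_err)]

    def _title(self) -> str:
        return "Two-state chemical denaturation fit"


class ChemicalDenaturationModel:
    """Two-state LFER model for an equilibrium urea denaturation curve.

    Parameters
    ----------
    curve : DenaturationCurve
        Must be in chemical mode.
    temperature : float
        Temperature (K) at which RT inside the Boltzmann factor is
        evaluated; isothermal titrations use the bath temperature.
    check_two_state : bool
        Reject curves where the two-state model does not beat a straight
        line by at least ``min_delta_aic`` AIC units (degenerate,
        transition-free data).
    """

    param_names = _CHEM_PARAMS

    def __init__(
        self,
        curve: DenaturationCurve,
        temperature: float | None = None,
        constants: Constants = DEFAULT_CONSTANTS,
        check_two_state: bool = True,
        min_delta_aic: float = 10.0,
    ):
        if curve.mode is not DenaturationMode.chemical:
            raise InvalidInputError("curve is not a chemical denaturation curve")
        self.curve = curve
        self.constants = constants
        self.temperature = constants.T_ref if temperature is None else float(temperature)
        self.check_two_state = check_two_state
        self.min_delta_aic = min_delta_aic

    @classmethod
    def from_dataframe(cls, df, *, probe="CD222", **kw) -> "ChemicalDenaturationModel":
        """Build from a DataFrame with ``perturbation``/``signal`` columns."""
        curve = DenaturationCurve(
            perturbation=df["perturbation"].to_numpy(),
            signal=df["signal"].to_numpy(),
            probe=probe,
            mode="chemical",
            sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        )
        return cls(curve, **kw)

    # -- initial guesses ---------------------------------------------------
    def _initial_guess(self) -> np.ndarray:
        p, s = self.curve.perturbation, self.curve.signal
        sm = smooth5(s)
        slope = np.gradient(sm, p)
        mid_idx = int(np.argmax(np.abs(slope)))
        u50 = float(p[mid_idx])
        aN, bN, aD, bD = edge_baseline_guess(p, s)
        m0 = self._m_from_width(p, s, (aN, bN, aD, bD))
        return np.array([m0, u50, aN, bN, aD, bD])

    def _m_from_width(self, p, s, baselines) -> float:
        aN, bN, aD, bD = baselines
        denom = (aN + bN * p) - (aD + bD * p)
        if np.any(np.abs(denom) < 1e-12):
            return 1.5
        f = np.clip((s - (aD + bD * p)) / denom, 0.0, 1.0)
        f = smooth5(f)
        # two-state: f crosses 0.9 and 0.1 at dG/RT = +-ln 9
        try:
            hi = np.interp(0.9, f[::-1], p[::-1])
            lo = np.interp(0.1, f[::-1], p[::-1])
        except Exception:
            return 1.5
        width = abs(lo - hi)
        if width < 1e-6 or not np.isfinite(width):
            return 1.5
        return _LN81 * self.constants.R * self.temperature / width

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> ChemicalFitResult:
        p, s = self.curve.perturbation, self.curve.signal
        T = self.temperature

        def model(u, m, u50, aN, bN, aD, bD):
            return two_state_signal(
                u, lfer_dG(u, m, u50), (aN, bN, aD, bD), T, R=self.constants.R
            )

        span = p[-1] - p[0]
        lo = np.array([1e-3, p[0] - 0.5 * span, -np.inf, -np.inf, -np.inf, -np.inf])
        hi = np.array([50.0, p[-1] + 0.5 * span, np.inf, np.inf, np.inf, np.inf])
        out = multistart_curve_fit(
            model,
            p,
            s,
            np.clip(self._initial_guess(), lo, hi),
            sigma=self.curve.sigma,
            bounds=(lo, hi),
            n_starts=n_starts,
            seed=seed,
            label="chemical denaturation",
        )
        if self.check_two_state:
            self._reject_degenerate(p, s, out.residual_norm)
        return ChemicalFitResult(
            param_names=self.param_names,
            popt=out.popt,
            pcov=out.pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
            temperature=T,
            curve=self.curve,
        )

    def _reject_degenerate(self, p, s, residual_norm) -> None:
        line_rss = float(np.sum((s - np.polyval(np.polyfit(p, s, 1), p)) ** 2))
        aic_line = aic_from_rss(line_rss, len(p), 2)
        aic_two_state = aic_from_rss(residual_norm**2, len(p), len(self.param_names))
        if aic_line - aic_two_state < self.min_delta_aic:
            raise FitFailureError(
                "two-state model not supported over a straight line "
                f"(delta AIC = {aic_line - aic_two_state:.1f} < {self.min_delta_aic})",
                best_residual=residual_norm,
            )


def fit_chemical_denaturation(
    curve: DenaturationCurve, T: float | None = None, **kw
) -> ChemicalFitResult:
    """Fit a urea denaturation curve; see :class:`ChemicalDenaturationModel`."""
    return ChemicalDenaturationModel(curve, temperature=T, **kw).fit()


# ---------------------------------------------------------------------------
# Thermal denaturation
# ---------------------------------------------------------------------------

_THERM_PARAMS = ["dH_m", "T_m", "alpha_N", "beta_N", "alpha_D", "beta_D"]


@dataclass
class ThermalFitResult(FitResultBase):
    """Fitted two-state thermal melt; dCp was held fixed during fitting."""

    dCp: float = 0.0
    n_residues: int = 0
    curve: DenaturationCurve | None = field(default=None, repr=False)

    @property
    def dH_m(self) -> float:
        return float(self.popt[0])

    @property
    def T_m(self) -> float:
        return float(self.popt[1])

    @property
    def baselines(self) -> tuple[float, float, float, float]:
        return tuple(float(v) for v in self.popt[2:6])

    def dG(self, T) -> np.ndarray:
        """Unfolding free energy at temperature T from the fitted melt."""
        return gibbs_helmholtz_dG(T, self.dH_m, self.T_m, self.dCp)

    def predict(self, T) -> np.ndarray:
        return two_state_signal(T, self.dG(np.asarray(T, dtype=float)), self.baselines, T)

    def _derived_rows(self):
        return [("dCp (fixed)", self.dCp, None)]

    def _title(self) -> str:
        return "Two-state thermal denaturation fit"


class ThermalDenaturationModel:
    """Gibbs-Helmholtz two-state model for a CD melting curve.

    ``n_residues`` sets the fixed heat-capacity increment
    dCp = 0.014 * n_residues kcal/(K*mol); it must be supplied because
    the empirical increment is per residue. The Boltzmann factor is
    evaluated at the running temperature of each point.
    """

    param_names = _THERM_PARAMS

    def __init__(
        self,
        curve: DenaturationCurve,
        n_residues: int,
        constants: Constants = DEFAULT_CONSTANTS,
        check_two_state: bool = True,
        min_delta_aic: float = 10.0,
    ):
        if curve.mode is not DenaturationMode.thermal:
            raise InvalidInputError("curve is not a thermal denaturation curve")
        if n_residues < 1:
            raise InvalidInputError("n_residues must be >= 1")
        self.curve = curve
        self.n_residues = int(n_residues)
        self.constants = constants
        self.dCp = constants.dCp_per_residue * self.n_residues
        self.check_two_state = check_two_state
        self.min_delta_aic = min_delta_aic

    def _initial_guess(self) -> np.ndarray:
        t, s = self.curve.perturbation, self.curve.signal
        sm = smooth5(s)
        # midpoint: last crossing of the mid-signal level scanning from
        # high temperature; robust against a cold-denaturation wing at
        # the low-T end of the scan
        k = max(2, len(t) // 5)
        mid = 0.5 * (float(np.mean(sm[:k])) + float(np.mean(sm[-k:])))
        signs = np.sign(sm - mid)
        crossings = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
        if len(crossings):
            Tm0 = float(t[crossings[-1]])
        else:
            slope = np.gradient(sm, t)
            Tm0 = float(t[int(np.argmax(np.abs(slope)))])
        aN, bN, aD, bD = edge_baseline_guess(t, s)
        width = self._transition_width(t, s, (aN, bN, aD, bD))
        # near T_m, dG ~ (dH_m/T_m)(T_m - T): width maps onto dH_m
        dH0 = _LN81 * self.constants.R * Tm0**2 / width if width else 60.0
        return np.array([dH0, Tm0, aN, bN, aD, bD])

    def _transition_width(self, t, s, baselines) -> float | None:
        aN, bN, aD, bD = baselines
        denom = (aN + bN * t) - (aD + bD * t)
        if np.any(np.abs(denom) < 1e-12):
            return None
        f = np.clip((s - (aD + bD * t)) / denom, 0.0, 1.0)
        f = smooth5(f)
        try:
            hi = np.interp(0.9, f[::-1], t[::-1])
            lo = np.interp(0.1, f[::-1], t[::-1])
        except Exception:
            return None
        width = abs(lo - hi)
        return width if (np.isfinite(width) and width > 1e-6) else None

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> ThermalFitResult:
        t, s = self.curve.perturbation, self.curve.signal
        dCp = self.dCp

        def model(T, dHm, Tm, aN, bN, aD, bD):
            dG = gibbs_helmholtz_dG(T, dHm, Tm, dCp)
            return two_state_signal(T, dG, (aN, bN, aD, bD), T, R=self.constants.R)

        # T_m constrained to the scanned temperature range; dH_m positive
        lo = np.array([1.0, t[0], -np.inf, -np.inf, -np.inf, -np.inf])
        hi = np.array([1000.0, t[-1], np.inf, np.inf, np.inf, np.inf])
        out = multistart_curve_fit(
            model,
            t,
            s,
            np.clip(self._initial_guess(), lo, hi),
            sigma=self.curve.sigma,
            bounds=(lo, hi),
            n_starts=n_starts,
            seed=seed,
            label="thermal denaturation",
        )
        if self.check_two_state:
            line_rss = float(np.sum((s - np.polyval(np.polyfit(t, s, 1), t)) ** 2))
            d_aic = aic_from_rss(line_rss, len(t), 2) - aic_from_rss(
                out.residual_norm**2, len(t), 6
            )
            if d_aic < self.min_delta_aic:
                raise FitFailureError(
                    f"two-state melt not supported (delta AIC = {d_aic:.1f})",
                    best_residual=out.residual_norm,
                )
        return ThermalFitResult(
            param_names=self.param_names,
            popt=out.popt,
            pcov=out.pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
            dCp=dCp,
            n_residues=self.n_residues,
            curve=self.curve,
        )


def fit_thermal_denaturation(
    curve: DenaturationCurve, n_residues: int, **kw
) -> ThermalFitResult:
    """Fit a thermal melt; see :class:`ThermalDenaturationModel`."""
    return ThermalDenaturationModel(curve, n_residues, **kw).fit()


def folded_fraction(
    curve: DenaturationCurve, fit: "ChemicalFitResult | ThermalFitResult"
) -> np.ndarray:
    """Normalize a curve to the folded fraction using fitted baselines.

    f_N = (S - D(P)) / (N(P) - D(P)) with N, D the fitted native and
    denatured baselines; noise-free two-state data map exactly onto the
    native population.
    """
    p, s = curve.perturbation, curve.signal
    aN, bN, aD, bD = fit.baselines
    denom = (aN + bN * p) - (aD + bD * p)
    if np.any(np.abs(denom) < 1e-12):
        raise DegenerateNormalizationError(
            "native and denatured baselines coincide within 1e-12"
        )
    return (s - (aD + bD * p)) / denom
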