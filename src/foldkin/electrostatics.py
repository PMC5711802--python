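"""Debye-Hueckel analysis of the ionic-strength dependence of stability.

Counter-ion clouds screen surface point charges; the screening length
scales with the square root of the ionic strength I, so for a protein
destabilized by surface charge clustering the unfolding free energy is
empirically linear in sqrt(I). The slope of an ordinary least-squares
fit of dG (or ddG) on sqrt(I) is the salt equilibrium m-value m_eq'
(kcal mol^-1 M^-0.5), the electrostatic analogue of the denaturant
m-value.

Thermal series carry (I, T_m, dH_m) from individual melts and are first
converted to ddG relative to a reference ionic strength with the
Schellman relation ddG = (dH_m,ref / T_m,ref) * (T_m - T_m,ref); the
choice of reference shifts the intercept but not the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .datasets import SaltSeries, SaltSeriesSource
from .exceptions import InvalidInputError

__all__ = [
    "SaltFitResult",
    "SaltDependenceModel",
    "thermal_series_to_ddG",
    "fit_debye_huckel_slope",
    "homologue_summary",
]


def thermal_series_to_ddG(series: SaltSeries, per_point_dH: bool = False) -> SaltSeries:
    """Convert a thermal (I, T_m, dH_m) series to Schellman ddG values.

    ddG_i = (dH_m,ref / T_m,ref) * (T_m,i - T_m,ref), zero at the
    reference point (``series.reference_index``, default the lowest I).
    With ``per_point_dH`` the enthalpy of each melt is used instead of
    the reference value.
    """
    if series.source is not SaltSeriesSource.thermal:
        raise InvalidInputError("series is not a thermal salt series")
    ref = series.reference_index
    tm_ref = series.T_m[ref]
    # the Schellman prefactor dH_m/T_m is anchored at the lowest-I melt
    # (the series' physical baseline) so that changing the zero point
    # only shifts the intercept of the sqrt(I) regression, never its
    # slope
    anchor = int(np.argmin(series.ionic_strength))
    dh_anchor = series.dH_m[anchor]
    if not np.isfinite(dh_anchor):
        raise InvalidInputError("anchor point lacks a dH_m value")
    dh = series.dH_m if per_point_dH else dh_anchor
    ddG = dh / series.T_m[anchor] * (series.T_m - tm_ref)
    return replace(series, dG=np.asarray(ddG, dtype=float), source=SaltSeriesSource.chemical)


@dataclass
class SaltFitResult:
    """Linear fit of free energy vs sqrt(ionic strength)."""

    m_eq_prime: float  # slope, kcal mol^-1 M^-0.5
    intercept: float  # kcal/mol
    m_eq_prime_err: float
    intercept_err: float
    r_squared: float
    n_points: int

    @property
    def std_errors(self) -> dict[str, float]:
        return {"m_eq_prime": self.m_eq_prime_err, "intercept": self.intercept_err}

    def predict(self, ionic_strength) -> np.ndarray:
        return self.intercept + self.m_eq_prime * np.sqrt(
            np.asarray(ionic_strength, dtype=float)
        )

    def summary(self) -> str:
        return (
            "Debye-Hueckel salt slope fit\n"
            f"m_eq' = {self.m_eq_prime:.4g} +- {self.m_eq_prime_err:.2g} "
            "kcal mol^-1 M^-0.5\n"
            f"intercept = {self.intercept:.4g} +- {self.intercept_err:.2g} kcal/mol\n"
            f"R^2 = {self.r_squared:.4f}  (n = {self.n_points})"
        )

    def to_dict(self) -> dict:
        return {
            "m_eq_prime": self.m_eq_prime,
            "intercept": self.intercept,
            "std_errors": self.std_errors,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


class SaltDependenceModel:
    """OLS regression of stability on sqrt(I) for one homologue."""

    def __init__(self, series: SaltSeries, per_point_dH: bool = False):
        if series.source is SaltSeriesSource.thermal:
            series = thermal_series_to_ddG(series, per_point_dH=per_point_dH)
        if series.dG is None:
            raise InvalidInputError("series carries no free-energy values")
        self.series = series

    def fit(self) -> SaltFitResult:
        x = np.sqrt(self.series.ionic_strength)
        y = self.series.dG
        res = stats.linregress(x, y)
        return SaltFitResult(
            m_eq_prime=float(res.slope),
            intercept=float(res.intercept),
            m_eq_prime_err=float(res.stderr),
            intercept_err=float(res.intercept_stderr),
            r_squared=float(res.rvalue**2),
            n_points=len(x),
        )


def fit_debye_huckel_slope(series: SaltSeries, **kw) -> SaltFitResult:
    """Fit dG (or Schellman ddG) vs sqrt(I); slope is m_eq'."""
    return SaltDependenceModel(series, **kw).fit()


def homologue_summary(fits: dict[str, SaltFitResult]) -> dict:
    """Mean salt m-value and SEM across homologues.

    Order-independent; with a single fit the SEM is reported as None.
    """
    if not fits:
        raise InvalidInputError("need at least one fit")
    labels = sorted(fits)
    slopes = np.array([fits[k].m_eq_prime for k in labels])
    mean = float(np.mean(slopes))
    sem = (
        float(np.std(slopes, ddof=1) / math.sqrt(len(slopes)))
        if len(slopes) > 1
        else None
    )
    return {
        "per_homologue": {k: fits[k].m_eq_prime for k in labels},
        "mean_m_eq_prime": mean,
        "sem_m_eq_prime": sem,
        "n": len(slopes),
    }
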