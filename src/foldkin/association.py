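"""Second-order dimerization and chasing-dissociation kinetics.

Two folded monomers N associate irreversibly on the stopped-flow time
scale, 2N -> N2 with d[N2]/dt = k_ass [N]^2. With equal starting
concentrations the signal follows the hyperbolic closed form

    S(t) = S0 + S_amp * (k_app t) / (1 + k_app t),    k_app = c_N * k_ass

where c_N is the post-mixing monomer concentration. Dissociation is
measured by chasing a labelled subunit out of preformed dimers with
excess unlabelled protein and fitting the fluorescence rise to a single
exponential, S(t) = c + a (1 - exp(-k_diss t)). The affinity is
K_d = k_diss / k_ass.

The apparent-rate convention k_app = c_N * k_ass is the package
default; the textbook monomer-loss convention (d[N]/dt = -2 k_ass [N]^2,
giving k_app = 2 c_N k_ass) is available through
``stoichiometry_factor=2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fitting import multistart_curve_fit
from ._results import FitResultBase
from .datasets import KineticTransient
from .exceptions import FitFailureError, InvalidInputError

__all__ = [
    "dimer_signal",
    "AssociationResult",
    "DissociationResult",
    "Affinity",
    "AssociationModel",
    "DissociationModel",
    "fit_association",
    "fit_dissociation",
    "compute_Kd",
    "c_N_from_premix",
]


def dimer_signal(t, S0, S_amp, k_app):
    """Hyperbolic second-order association signal.

    S(t) = S0 + S_amp (k_app t)/(1 + k_app t); starts at S0, saturates
    at S0 + S_amp, half-saturated at t = 1/k_app.
    """
    t = np.asarray(t, dtype=float)
    x = k_app * t
    return S0 + S_amp * x / (1.0 + x)


def c_N_from_premix(c_premix: float, mix_ratio: tuple[int, int]) -> float:
    """Post-mixing monomer concentration from a volumetric mixing ratio.

    A ratio of (1, 11) means one volume of protein into eleven volumes
    of buffer: c_N = c_premix * 1 / 12.
    """
    a, b = mix_ratio
    if a <= 0 or b <= 0:
        raise InvalidInputError("mixing-ratio parts must be positive")
    return c_premix * a / (a + b)


_ASSOC_PARAMS = ["S0", "S_amp", "k_app"]


@dataclass
class AssociationResult(FitResultBase):
    """Fitted dimerization transient; k_ass = k_app / c_N by construction."""

    c_N: float = np.nan  # M, post-mixing monomer concentration
    stoichiometry_factor: float = 1.0

    @property
    def S0(self) -> float:
        return float(self.popt[0])

    @property
    def S_amp(self) -> float:
        return float(self.popt[1])

    @property
    def k_app(self) -> float:
        return float(self.popt[2])

    @property
    def k_ass(self) -> float:
        return self.k_app / (self.stoichiometry_factor * self.c_N)

    @property
    def k_ass_err(self) -> float:
        # c_N treated as exact
        return float(self.bse["k_app"]) / (self.stoichiometry_factor * self.c_N)

    def predict(self, t) -> np.ndarray:
        return dimer_signal(t, *self.popt)

    def _derived_rows(self):
        return [("k_ass", self.k_ass, self.k_ass_err)]

    def _title(self) -> str:
        return "Second-order association fit"


class AssociationModel:
    """Second-order dimerization model for a stopped-flow trace.

    Parameters
    ----------
    transient : KineticTransient
    c_N : float
        Post-mixing monomer concentration in M (use
        :func:`c_N_from_premix` for premix concentration + mixing ratio).
    stoichiometry_factor : float
        1 for the k_app = c_N k_ass convention (default); 2 for the
        monomer-loss convention k_app = 2 c_N k_ass.
    fit_start : float
        Drop points before this time (s); early-time deviations from
        trace oligomeric populations can be excluded this way.
    """

    param_names = _ASSOC_PARAMS

    def __init__(
        self,
        transient: KineticTransient,
        c_N: float,
        stoichiometry_factor: float = 1.0,
        fit_start: float = 0.0,
    ):
        if c_N <= 0:
            raise InvalidInputError("c_N must be positive")
        if stoichiometry_factor <= 0:
            raise InvalidInputError("stoichiometry_factor must be positive")
        self.transient = transient
        self.c_N = float(c_N)
        self.stoichiometry_factor = float(stoichiometry_factor)
        mask = transient.time >= fit_start
        if mask.sum() < 5:
            raise InvalidInputError("fewer than 5 points after fit_start")
        self._t = transient.time[mask]
        self._s = transient.signal[mask]

    def _initial_guess(self) -> np.ndarray:
        t, s = self._t, self._s
        S0 = float(s[0])
        amp = float(s[-1] - s[0])
        if amp == 0.0:
            amp = float(np.ptp(s)) or 1.0
        # half-saturation time: first crossing of the mid-signal
        target = S0 + amp / 2.0
        idx = np.argmin(np.abs(s - target))
        t_half = max(float(t[idx]), float(t[1]) if t[0] == 0 else float(t[0]))
        return np.array([S0, amp, 1.0 / t_half])

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> AssociationResult:
        out = multistart_curve_fit(
            dimer_signal,
            self._t,
            self._s,
            self._initial_guess(),
            n_starts=n_starts,
            seed=seed,
            label="association",
        )
        return AssociationResult(
            param_names=self.param_names,
            popt=out.popt,
            pcov=out.pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
            c_N=self.c_N,
            stoichiometry_factor=self.stoichiometry_factor,
        )


def fit_association(
    transient: KineticTransient, c_N: float, **kw
) -> AssociationResult:
    """Fit a dimerization transient; see :class:`AssociationModel`."""
    return AssociationModel(transient, c_N, **kw).fit()


_DISS_PARAMS = ["c", "a", "k_diss"]


@dataclass
class DissociationResult(FitResultBase):
    """Mono-exponential rise fit to a chasing transient."""

    @property
    def offset(self) -> float:
        return float(self.popt[0])

    @property
    def amplitude(self) -> float:
        return float(self.popt[1])

    @property
    def k_diss(self) -> float:
        return float(self.popt[2])

    @property
    def k_diss_err(self) -> float:
        return float(self.bse["k_diss"])

    def predict(self, t) -> np.ndarray:
        c, a, k = self.popt
        return c + a * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))

    def _title(self) -> str:
        return "Chasing-dissociation fit"


class DissociationModel:
    """Mono-exponential rise, S(t) = c + a (1 - exp(-k_diss t))."""

    param_names = _DISS_PARAMS

    def __init__(self, transient: KineticTransient, fit_start: float = 0.0):
        self.transient = transient
        mask = transient.time >= fit_start
        if mask.sum() < 5:
            raise InvalidInputError("fewer than 5 points after fit_start")
        self._t = transient.time[mask]
        self._s = transient.signal[mask]
        n = max(3, len(self._s) // 10)
        if np.mean(self._s[-n:]) <= np.mean(self._s[:n]):
            warnings.warn(
                "dissociation transient does not rise; check experiment type",
                stacklevel=2,
            )

    def _initial_guess(self) -> np.ndarray:
        t, s = self._t, self._s
        c0 = float(s[0])
        n = max(3, len(s) // 10)
        a0 = float(np.mean(s[-n:]) - c0)
        if a0 == 0.0:
            a0 = float(np.ptp(s)) or 1.0
        target = c0 + a0 * (1.0 - math.exp(-1.0))
        idx = int(np.argmin(np.abs(s - target)))
        t63 = float(t[idx]) if t[idx] > 0 else float(t[len(t) // 2])
        return np.array([c0, a0, 1.0 / max(t63, 1e-12)])

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> DissociationResult:
        def model(t, c, a, k):
            return c + a * (1.0 - np.exp(-k * t))

        out = multistart_curve_fit(
            model,
            self._t,
            self._s,
            self._initial_guess(),
            n_starts=n_starts,
            seed=seed,
            label="dissociation",
        )
        c, a, k = out.popt
        amp_scale = max(float(np.ptp(self._s)), abs(float(np.mean(self._s))), 1e-300)
        if abs(a) < 1e-6 * amp_scale or k <= 0:
            raise FitFailureError(
                "dissociation amplitude degenerate; k_diss unidentifiable",
                best_residual=out.residual_norm,
            )
        return DissociationResult(
            param_names=self.param_names,
            popt=out.popt,
            pcov=out.pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
        )


def fit_dissociation(transient: KineticTransient, **kw) -> DissociationResult:
    """Fit a chasing transient; see :class:`DissociationModel`."""
    return DissociationModel(transient, **kw).fit()


@dataclass(frozen=True)
class Affinity:
    """Equilibrium dissociation constant K_d = k_diss / k_ass (M)."""

    K_d: float
    std_error: float = 0.0

    @property
    def K_d_nM(self) -> float:
        return self.K_d * 1e9

    @property
    def std_error_nM(self) -> float:
        return self.std_error * 1e9


def compute_Kd(
    k_diss: float,
    k_ass: float,
    sigma_k_diss: float = 0.0,
    sigma_k_ass: float = 0.0,
) -> Affinity:
    """Affinity from the kinetic rate constants, with propagated error.

    K_d = k_diss/k_ass; sigma_Kd = K_d sqrt((s_diss/k_diss)^2 +
    (s_ass/k_ass)^2).
    """
    if k_diss <= 0 or k_ass <= 0:
        raise InvalidInputError("rate constants must be positive")
    kd = k_diss / k_ass
    err = kd * math.sqrt((sigma_k_diss / k_diss) ** 2 + (sigma_k_ass / k_ass) ** 2)
    return Affinity(K_d=kd, std_error=err)
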