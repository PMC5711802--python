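"""Stopped-flow folding kinetics: exponential transients and chevrons.

A single mixing experiment relaxes with one observed rate constant,
k_obs = k_f' + k_u' (the sum of the microscopic rate constants at the
final denaturant concentration), and is fitted as

    S(t) = a exp(-k_obs t) + b t + c

where the linear term absorbs slow instrumental drift (photobleaching,
sample diffusion). The denaturant dependence of k_obs is the chevron,

    log k_obs(u) = log[k_f exp(-m_f u / RT) + k_u exp(+m_u u / RT)]

whose limbs extrapolate to the folding and unfolding rate constants in
water and whose slopes are the kinetic m-values (m_f = m_TS-D,
m_u = m_TS-N, kcal/(M*mol)). Derived quantities: dG = -RT ln(k_u/k_f)
and the Tanford beta_T = m_f / (m_f + m_u).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fitting import multistart_curve_fit
from ._results import FitResultBase
from .constants import DEFAULT_CONSTANTS, Constants
from .datasets import ChevronDataset, KineticTransient
from .exceptions import InvalidInputError, UnderdeterminedFitError

__all__ = [
    "exponential_with_drift",
    "chevron_log10_k_obs",
    "ExponentialFit",
    "ChevronFitResult",
    "TransientModel",
    "ChevronModel",
    "fit_exponential_with_drift",
    "fit_chevron",
    "dG_from_rates",
    "tanford_beta",
    "consistency_report",
]

_LN10 = math.log(10.0)


def exponential_with_drift(t, a, k_obs, b, c):
    """S(t) = a exp(-k_obs t) + b t + c."""
    t = np.asarray(t, dtype=float)
    return a * np.exp(-k_obs * t) + b * t + c


def chevron_log10_k_obs(urea, k_f, m_f, k_u, m_u, T=DEFAULT_CONSTANTS.T_ref,
                        R=DEFAULT_CONSTANTS.R):
    """log10 of the two-state chevron, evaluated via log-sum-exp.

    Stable across the full dynamic range of the two limbs.
    """
    u = np.asarray(urea, dtype=float)
    RT = R * T
    log_fold = np.log(k_f) - m_f * u / RT
    log_unfold = np.log(k_u) + m_u * u / RT
    return np.logaddexp(log_fold, log_unfold) / _LN10


def dG_from_rates(k_f: float, k_u: float, T: float = DEFAULT_CONSTANTS.T_ref,
                  R: float = DEFAULT_CONSTANTS.R) -> float:
    """Equilibrium stability from rate constants: dG = -RT ln(k_u/k_f)."""
    if k_f <= 0 or k_u <= 0:
        raise InvalidInputError("rate constants must be positive")
    return -R * T * math.log(k_u / k_f)


def tanford_beta(m_f: float, m_u: float) -> float:
    """Tanford beta_T = m_f / (m_f + m_u); ~1 means native-like TS."""
    if m_f + m_u == 0:
        raise InvalidInputError("m_f + m_u must be non-zero")
    return m_f / (m_f + m_u)


# ---------------------------------------------------------------------------
# Transient fitting
# ---------------------------------------------------------------------------

_EXP_PARAMS = ["a", "k_obs", "b", "c"]


@dataclass
class ExponentialFit(FitResultBase):
    transient: KineticTransient | None = field(default=None, repr=False)

    @property
    def a(self) -> float:
        return float(self.popt[0])

    @property
    def k_obs(self) -> float:
        return float(self.popt[1])

    @property
    def b(self) -> float:
        return float(self.popt[2])

    @property
    def c(self) -> float:
        return float(self.popt[3])

    def predict(self, t) -> np.ndarray:
        return exponential_with_drift(t, *self.popt)

    def _title(self) -> str:
        return "Single-exponential transient fit (with drift)"


class TransientModel:
    """Single exponential with linear baseline drift for one trace.

    ``dead_time`` seconds at the start of the trace are excluded before
    fitting (instrument mixing artefacts); default 0.
    """

    param_names = _EXP_PARAMS

    def __init__(self, transient: KineticTransient, dead_time: float = 0.0):
        self.transient = transient
        mask = transient.time >= dead_time
        if mask.sum() < 5:
            raise InvalidInputError("fewer than 5 points after dead time")
        self._t = transient.time[mask]
        self._s = transient.signal[mask]

    def _initial_guess(self) -> np.ndarray:
        t, s = self._t, self._s
        n_tail = max(3, len(t) // 10)
        tail_mean = float(np.mean(s[-n_tail:]))
        amp0 = float(s[0] - tail_mean)
        if amp0 == 0.0:
            amp0 = float(np.ptp(s)) or 1.0
        # log-linear regression of |S - tail mean| over the decaying part
        dev = np.abs(s - tail_mean)
        sel = dev > 0.05 * np.max(dev)
        k0 = 1.0 / max(t[-1], 1e-12)
        if sel.sum() >= 3:
            slope = np.polyfit(t[sel], np.log(dev[sel]), 1)[0]
            if slope < 0:
                k0 = -slope
        return np.array([amp0, k0, 0.0, tail_mean])

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> ExponentialFit:
        out = multistart_curve_fit(
            exponential_with_drift,
            self._t,
            self._s,
            self._initial_guess(),
            n_starts=n_starts,
            seed=seed,
            label="transient",
        )
        k = out.popt[1]
        if k > 0 and self._t[-1] - self._t[0] < 3.0 / k:
            warnings.warn(
                "transient covers less than 3/k_obs of decay; "
                "rate may be poorly constrained",
                stacklevel=2,
            )
        return ExponentialFit(
            param_names=self.param_names,
            popt=out.popt,
            pcov=out.pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
            transient=self.transient,
        )


def fit_exponential_with_drift(
    transient: KineticTransient, dead_time: float = 0.0
) -> ExponentialFit:
    """Fit S(t) = a exp(-k_obs t) + b t + c to one stopped-flow trace."""
    return TransientModel(transient, dead_time=dead_time).fit()


# ---------------------------------------------------------------------------
# Chevron fitting
# ---------------------------------------------------------------------------

_CHEV_PARAMS = ["k_f", "m_TS_D", "k_u", "m_TS_N"]


@dataclass
class ChevronFitResult(FitResultBase):
    """Two-state chevron fit with derived kinetic thermodynamics.

    The fit is performed in (log10 k_f, m_f, log10 k_u, m_u) space for
    positivity; reported parameters and errors are back-transformed.
    """

    temperature: float = DEFAULT_CONSTANTS.T_ref
    dataset: ChevronDataset | None = field(default=None, repr=False)

    @property
    def k_f(self) -> float:
        return float(self.popt[0])

    @property
    def m_TS_D(self) -> float:
        return float(self.popt[1])

    @property
    def k_u(self) -> float:
        return float(self.popt[2])

    @property
    def m_TS_N(self) -> float:
        return float(self.popt[3])

    # field-standard aliases
    m_f = m_TS_D
    m_u = m_TS_N

    @property
    def dG_kin(self) -> float:
        return dG_from_rates(self.k_f, self.k_u, self.temperature)

    @property
    def beta_T(self) -> float:
        return tanford_beta(self.m_TS_D, self.m_TS_N)

    @property
    def m_kin_sum(self) -> float:
        return self.m_TS_D + self.m_TS_N

    @property
    def derived(self) -> dict[str, float]:
        return {
            "dG_kin": self.dG_kin,
            "beta_T": self.beta_T,
            "m_kin_sum": self.m_kin_sum,
        }

    def predict_log10(self, urea) -> np.ndarray:
        return chevron_log10_k_obs(
            urea, self.k_f, self.m_TS_D, self.k_u, self.m_TS_N, self.temperature
        )

    def predict(self, urea) -> np.ndarray:
        return 10.0 ** self.predict_log10(urea)

    def _derived_rows(self):
        return [
            ("dG_kin", self.dG_kin, None),
            ("beta_T", self.beta_T, None),
            ("m_f + m_u", self.m_kin_sum, None),
        ]

    def _title(self) -> str:
        return "Two-state chevron fit"


class ChevronModel:
    """Barrier-limited two-state chevron fitted in log10(k_obs) space.

    Residuals are taken on log10(k_obs), equalizing the influence of
    the two limbs over the ~4 decades a chevron spans.
    """

    param_names = _CHEV_PARAMS

    def __init__(self, dataset: ChevronDataset, constants: Constants = DEFAULT_CONSTANTS):
        self.dataset = dataset
        self.constants = constants

    def _limb_guesses(self) -> np.ndarray:
        u = self.dataset.urea
        logk = np.log10(self.dataset.k_obs)
        RT = self.constants.R * self.dataset.temperature
        i_min = int(np.argmin(logk))
        if i_min < 2 or i_min > len(u) - 3:
            raise UnderdeterminedFitError(
                "chevron minimum not bracketed: need >= 2 points on each limb"
            )
        # log-linear fit per limb: slope_fold = -m_f/(RT ln10), intercept log10 k_f
        sf, cf = np.polyfit(u[: i_min + 1], logk[: i_min + 1], 1)
        su, cu = np.polyfit(u[i_min:], logk[i_min:], 1)
        m_f0 = max(-sf * RT * _LN10, 0.05)
        m_u0 = max(su * RT * _LN10, 0.01)
        return np.array([cf, m_f0, cu, m_u0])  # (log10 k_f, m_f, log10 k_u, m_u)

    def fit(self, *, n_starts: int = 5, seed: int = 0) -> ChevronFitResult:
        u = self.dataset.urea
        y = np.log10(self.dataset.k_obs)
        T = self.dataset.temperature
        R = self.constants.R
        sigma = None
        if self.dataset.sigma is not None:
            # delta method: sigma on log10 k from sigma on k
            sigma = self.dataset.sigma / (self.dataset.k_obs * _LN10)

        def model(uu, log_kf, m_f, log_ku, m_u):
            return chevron_log10_k_obs(uu, 10.0**log_kf, m_f, 10.0**log_ku, m_u, T, R)

        out = multistart_curve_fit(
            model, u, y, self._limb_guesses(), sigma=sigma,
            n_starts=n_starts, seed=seed, label="chevron",
        )
        popt, pcov = self._back_transform(out.popt, out.pcov)
        return ChevronFitResult(
            param_names=self.param_names,
            popt=popt,
            pcov=pcov,
            residual_norm=out.residual_norm,
            n_points=out.n_points,
            temperature=T,
            dataset=self.dataset,
        )

    @staticmethod
    def _back_transform(popt_log, pcov_log):
        """Map (log10 k, m) estimates/covariance to linear-rate space."""
        k_f = 10.0 ** popt_log[0]
        k_u = 10.0 ** popt_log[2]
        popt = np.array([k_f, popt_log[1], k_u, popt_log[3]])
        jac = np.diag([k_f * _LN10, 1.0, k_u * _LN10, 1.0])
        pcov = jac @ pcov_log @ jac.T
        return popt, pcov


def fit_chevron(dataset: ChevronDataset, **kw) -> ChevronFitResult:
    """Fit the two-state chevron model; see :class:`ChevronModel`."""
    return ChevronModel(dataset, **kw).fit()


# ---------------------------------------------------------------------------
# Equilibrium / kinetic consistency
# ---------------------------------------------------------------------------


def consistency_report(
    dG_eq: float,
    m_eq: float,
    dG_kin: float,
    m_kin_sum: float,
    threshold: float = 0.20,
) -> dict:
    """Compare equilibrium and kinetic estimates of stability and m-value.

    Accepts either raw numbers or fitted result objects via
    :func:`consistency_report_from_fits`. Relative discrepancy is
    |difference| / mean; the dataset is flagged two-state consistent when
    both discrepancies are at or below ``threshold``.
    """
    rel_dG = abs(dG_eq - dG_kin) / ((dG_eq + dG_kin) / 2.0)
    rel_m = abs(m_eq - m_kin_sum) / ((m_eq + m_kin_sum) / 2.0)
    return {
        "dG_eq": dG_eq,
        "dG_kin": dG_kin,
        "m_eq": m_eq,
        "m_kin_sum": m_kin_sum,
        "rel_discrepancy_dG": rel_dG,
        "rel_discrepancy_m": rel_m,
        "two_state_consistent": bool(rel_dG <= threshold and rel_m <= threshold),
    }


def consistency_report_from_fits(eq, kin, threshold: float = 0.20) -> dict:
    """Consistency record from a ChemicalFitResult and a ChevronFitResult."""
    return consistency_report(
        eq.dG_DN, eq.m_DN, kin.dG_kin, kin.m_kin_sum, threshold=threshold
    )
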