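"""Base class for fit results (statsmodels-flavoured surface)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FitResultBase:
    """Common surface of all fitted models.

    Attributes
    ----------
    param_names : list of str
        Names of the free parameters, in fit order.
    popt, pcov : ndarray
        Point estimates and their covariance.
    residual_norm : float
        Euclidean norm of the residual vector at the optimum.
    n_points : int
        Number of data points fitted.
    """

    param_names: list[str] = field(default_factory=list)
    popt: np.ndarray = field(default_factory=lambda: np.array([]))
    pcov: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    residual_norm: float = np.nan
    n_points: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.popt, index=self.param_names, name="estimate")

    @property
    def bse(self) -> pd.Series:
        err = np.sqrt(np.clip(np.diag(self.pcov), 0.0, np.inf))
        return pd.Series(err, index=self.param_names, name="std_err")

    @property
    def std_errors(self) -> dict[str, float]:
        return dict(self.bse)

    @property
    def covariance(self) -> np.ndarray:
        return self.pcov

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcov, index=self.param_names, columns=self.param_names)

    @property
    def dof(self) -> int:
        return max(self.n_points - len(self.param_names), 1)

    def _derived_rows(self) -> list[tuple[str, float, float | None]]:
        """(name, value, std error or None) rows appended to summary()."""
        return []

    def _title(self) -> str:
        return type(self).__name__

    def summary(self) -> str:
        lines = [self._title(), "=" * len(self._title())]
        lines.append(f"n points: {self.n_points}   residual norm: {self.residual_norm:.4g}")
        lines.append(f"{'parameter':<14}{'estimate':>14}{'std err':>12}")
        for name, val, err in zip(self.param_names, self.popt, self.bse):
            lines.append(f"{name:<14}{val:>14.5g}{err:>12.3g}")
        derived = self._derived_rows()
        if derived:
            lines.append("derived:")
            for name, val, err in derived:
                e = f"{err:>12.3g}" if err is not None else " " * 12
                lines.append(f"{name:<14}{val:>14.5g}{e}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "parameters": {n: float(v) for n, v in zip(self.param_names, self.popt)},
            "std_errors": {n: float(v) for n, v in zip(self.param_names, self.bse)},
            "covariance": np.asarray(self.pcov).tolist(),
            "residual_norm": float(self.residual_norm),
            "n_points": int(self.n_points),
        }
        derived = {n: float(v) for n, v, _ in self._derived_rows()}
        if derived:
            out["derived"] = derived
        return out
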