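"""In-memory containers for the experimental data types.

All containers are plain frozen dataclasses wrapping numpy arrays; they
validate their invariants on construction and are what the model classes
are built from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError


class Probe(str, enum.Enum):
    """Spectroscopic probe of an equilibrium denaturation curve."""

    CD222 = "CD222"
    TrpFluorescence = "TrpFluorescence"


class DenaturationMode(str, enum.Enum):
    chemical = "chemical"
    thermal = "thermal"


class ExperimentType(str, enum.Enum):
    folding = "folding"
    unfolding = "unfolding"
    association = "association"
    dissociation = "dissociation"


@dataclass(frozen=True)
class Condition:
    """Solution condition metadata attached to a curve."""

    pH: float | None = None
    ionic_strength: float | None = None  # M
    label: str = ""


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DenaturationCurve:
    """One equilibrium denaturation experiment.

    ``perturbation`` is urea concentration in M (chemical mode) or
    temperature in K (thermal mode); ``signal`` is the raw spectroscopic
    reading (CD ellipticity at 222 nm or Trp fluorescence at 330 nm) in
    arbitrary units. ``sigma`` optionally carries per-point errors.
    """

    perturbation: np.ndarray
    signal: np.ndarray
    probe: Probe = Probe.CD222
    mode: DenaturationMode = DenaturationMode.chemical
    condition: Condition = field(default_factory=Condition)
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = _as_float_array(self.perturbation, "perturbation")
        s = _as_float_array(self.signal, "signal")
        object.__setattr__(self, "perturbation", p)
        object.__setattr__(self, "signal", s)
        if self.sigma is not None:
            sg = _as_float_array(self.sigma, "sigma")
            if sg.shape != p.shape:
                raise InvalidInputError("sigma length mismatch")
            object.__setattr__(self, "sigma", sg)
        if p.shape != s.shape:
            raise InvalidInputError("perturbation and signal length mismatch")
        if len(p) < 8:
            raise InvalidInputError(
                "need >= 8 points to constrain a 6-parameter two-state fit"
            )
        if not np.all(np.diff(p) > 0):
            raise InvalidInputError("perturbation must be strictly increasing")
        mode = DenaturationMode(self.mode)
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "probe", Probe(self.probe))
        if mode is DenaturationMode.chemical:
            if p[0] < 0 or p[-1] > 12:
                raise InvalidInputError("chemical perturbation must lie in [0, 12] M")
        else:
            if p[0] < 250 or p[-1] > 400:
                raise InvalidInputError("thermal perturbation must lie in [250, 400] K")

    def __len__(self) -> int:
        return len(self.perturbation)

    def with_signal(self, signal: np.ndarray) -> "DenaturationCurve":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass(frozen=True)
class TransientMeta:
    experiment: ExperimentType = ExperimentType.folding
    final_urea: float | None = None  # M, after mixing
    label: str = ""


@dataclass(frozen=True)
class KineticTransient:
    """One stopped-flow trace: time (s) vs fluorescence signal (a.u.)."""

    time: np.ndarray
    signal: np.ndarray
    meta: TransientMeta = field(default_factory=TransientMeta)

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        s = _as_float_array(self.signal, "signal")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape:
            raise InvalidInputError("time and signal length mismatch")
        if len(t) < 20:
            raise InvalidInputError("transient needs >= 20 points")
        if t[0] < 0:
            raise InvalidInputError("time must start at >= 0")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class ChevronDataset:
    """Observed relaxation rate constants vs final urea concentration."""

    urea: np.ndarray  # M
    k_obs: np.ndarray  # 1/s
    temperature: float = 298.0  # K
    sigma: np.ndarray | None = None  # optional errors on k_obs

    def __post_init__(self) -> None:
        u = _as_float_array(self.urea, "urea")
        k = _as_float_array(self.k_obs, "k_obs")
        object.__setattr__(self, "urea", u)
        object.__setattr__(self, "k_obs", k)
        if u.shape != k.shape:
            raise InvalidInputError("urea and k_obs length mismatch")
        if len(u) < 6:
            raise InvalidInputError("chevron needs >= 6 points")
        if np.any(k <= 0):
            raise InvalidInputError("all k_obs must be positive")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")
        if self.sigma is not None:
            sg = _as_float_array(self.sigma, "sigma")
            if sg.shape != u.shape:
                raise InvalidInputError("sigma length mismatch")
            object.__setattr__(self, "sigma", sg)

    def __len__(self) -> int:
        return len(self.urea)


class SaltSeriesSource(str, enum.Enum):
    chemical = "chemical"
    thermal = "thermal"


@dataclass(frozen=True)
class SaltSeries:
    """Stability vs ionic strength.

    Chemical source: (I, dG) pairs of absolute unfolding free energies.
    Thermal source: (I, T_m, dH_m) triples from individual melts; the
    Schellman conversion turns these into ddG relative to a reference
    point (default: lowest I).
    """

    ionic_strength: np.ndarray  # M
    dG: np.ndarray | None = None  # kcal/mol
    T_m: np.ndarray | None = None  # K
    dH_m: np.ndarray | None = None  # kcal/mol
    source: SaltSeriesSource = SaltSeriesSource.chemical
    reference_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        i = _as_float_array(self.ionic_strength, "ionic_strength")
        object.__setattr__(self, "ionic_strength", i)
        object.__setattr__(self, "source", SaltSeriesSource(self.source))
        if np.any(i <= 0):
            raise InvalidInputError("ionic strengths must be positive")
        if len(i) < 3:
            raise InvalidInputError("need >= 3 points for a slope with error")
        if self.source is SaltSeriesSource.chemical:
            if self.dG is None:
                raise InvalidInputError("chemical salt series requires dG values")
            g = _as_float_array(self.dG, "dG")
            if g.shape != i.shape:
                raise InvalidInputError("dG length mismatch")
            object.__setattr__(self, "dG", g)
        else:
            if self.T_m is None or self.dH_m is None:
                raise InvalidInputError("thermal salt series requires T_m and dH_m")
            tm = _as_float_array(self.T_m, "T_m")
            dh = _as_float_array(self.dH_m, "dH_m")
            if tm.shape != i.shape or dh.shape != i.shape:
                raise InvalidInputError("T_m/dH_m length mismatch")
            object.__setattr__(self, "T_m", tm)
            object.__setattr__(self, "dH_m", dh)
        if not (0 <= self.reference_index < len(i)):
            raise InvalidInputError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.ionic_strength)
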