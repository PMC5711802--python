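"""Seeded synthetic-data generators with stored ground truth.

Raw spectroscopic records for spidroin NTDs are not publicly deposited,
so parameter-recovery testing runs on synthetic data produced by the
same forward models the fitting layer assumes: sigmoidal two-state
denaturation curves with sloping baselines, exponential stopped-flow
transients with linear drift, hyperbolic second-order association
traces, mono-exponential dissociation rises, and two-limb chevrons.
Gaussian i.i.d. noise is added at a stated fraction of the signal
amplitude (absolute on log10 k_obs for chevrons). Identical
(scenario, seed) pairs give identical arrays.

Per-homologue presets carry the published central parameter values for
the four MaSp1 NTDs (Latrodectus hesperus "Lh", L. geometricus "Lg",
Nephila clavipes "Nc", Euprosthenops australis "Ea") so that scenarios
can be generated under realistic conditions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_CONSTANTS
from .datasets import (
    ChevronDataset,
    Condition,
    DenaturationCurve,
    ExperimentType,
    KineticTransient,
    Probe,
    SaltSeries,
    TransientMeta,
)
from .equilibrium import gibbs_helmholtz_dG, lfer_dG, two_state_signal
from .association import dimer_signal
from .exceptions import InvalidInputError
from .kinetics import chevron_log10_k_obs, exponential_with_drift

__all__ = [
    "ScenarioKind",
    "ScenarioSpec",
    "HomologuePreset",
    "preset",
    "PRESETS",
    "generate",
    "default_scenario",
    "generate_salt_melt_curves",
    "N_RESIDUES_DEFAULT",
]

#: Residue count used for synthetic thermal scenarios (MaSp1 NTD length scale).
N_RESIDUES_DEFAULT = 130


class ScenarioKind(str, enum.Enum):
    chemical_curve = "chemical_curve"
    thermal_curve = "thermal_curve"
    folding_transient = "folding_transient"
    association_transient = "association_transient"
    dissociation_transient = "dissociation_transient"
    chevron = "chevron"
    salt_series = "salt_series"


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level and optional extra linear drift.

    ``sigma`` is a fraction of the noise-free signal amplitude unless
    ``absolute`` is set (chevron noise is always absolute, on log10
    k_obs). ``drift_b`` adds b*t on top of the forward model.
    """

    sigma: float = 0.0
    drift_b: float = 0.0
    absolute: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")


@dataclass(frozen=True)
class GridSpec:
    start: float
    stop: float
    n: int
    log: bool = False

    def values(self) -> np.ndarray:
        if self.log:
            return np.geomspace(self.start, self.stop, self.n)
        return np.linspace(self.start, self.stop, self.n)


@dataclass(frozen=True)
class ScenarioSpec:
    kind: ScenarioKind
    truth: dict
    grid: GridSpec
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScenarioKind(self.kind))


@dataclass(frozen=True)
class HomologuePreset:
    """Published central parameter values for one MaSp1 NTD homologue."""

    label: str
    # equilibrium chemical denaturation, per probe: (m_DN, urea50)
    equilibrium: dict
    # thermal: (T_m, dH_m)
    T_m: float
    dH_m: float
    # chevron: (k_f, m_f, k_u, m_u)
    k_f: float
    m_f: float
    k_u: float
    m_u: float
    # association/dissociation
    k_ass: float
    k_diss: float
    # salt analysis slope, kcal mol^-1 M^-0.5
    m_eq_prime: float
    n_residues: int = N_RESIDUES_DEFAULT


PRESETS: dict[str, HomologuePreset] = {
    "Lh": HomologuePreset(
        label="Lh",
        equilibrium={"CD222": (1.64, 3.09), "TrpFluorescence": (1.58, 3.20)},
        T_m=329.9, dH_m=54.8,
        k_f=10123.0, m_f=1.29, k_u=4.67, m_u=0.22,
        k_ass=2.19e9, k_diss=0.31,
        m_eq_prime=3.5,
    ),
    "Lg": HomologuePreset(
        label="Lg",
        equilibrium={"CD222": (1.46, 3.39), "TrpFluorescence": (1.53, 3.34)},
        T_m=331.0, dH_m=50.1,
        k_f=11899.0, m_f=1.09, k_u=5.34, m_u=0.22,
        k_ass=1.39e9, k_diss=0.64,
        m_eq_prime=3.4,
    ),
    "Nc": HomologuePreset(
        label="Nc",
        equilibrium={"CD222": (1.59, 2.19), "TrpFluorescence": (1.67, 2.18)},
        T_m=326.8, dH_m=54.3,
        k_f=3652.0, m_f=1.39, k_u=12.16, m_u=0.28,
        k_ass=2.58e9, k_diss=1.88,
        m_eq_prime=3.4,
    ),
    "Ea": HomologuePreset(
        label="Ea",
        equilibrium={"CD222": (1.69, 3.30), "TrpFluorescence": (1.69, 3.31)},
        T_m=337.0, dH_m=67.5,
        k_f=13257.0, m_f=1.20, k_u=3.28, m_u=0.23,
        k_ass=1.58e9, k_diss=1.68,
        m_eq_prime=3.6,
    ),
}


def preset(label: str) -> HomologuePreset:
    """Published parameter preset for homologue 'Lh', 'Lg', 'Nc' or 'Ea'."""
    try:
        return PRESETS[label]
    except KeyError:
        raise InvalidInputError(f"unknown homologue label {label!r}") from None


# Default experimental designs: urea titration 0-8 M at 33 points,
# melts 278-368 K at 1 K, transients log-spaced 1e-4-10 s at 500
# points, chevron 0.5-8 M at 16 points.
_DEFAULT_GRIDS = {
    ScenarioKind.chemical_curve: GridSpec(0.0, 8.0, 33),
    ScenarioKind.thermal_curve: GridSpec(278.0, 368.0, 91),
    ScenarioKind.folding_transient: GridSpec(1e-4, 10.0, 500, log=True),
    ScenarioKind.association_transient: GridSpec(1e-4, 10.0, 500, log=True),
    ScenarioKind.dissociation_transient: GridSpec(1e-4, 10.0, 500, log=True),
    ScenarioKind.chevron: GridSpec(0.5, 8.0, 16),
    ScenarioKind.salt_series: GridSpec(0.041, 1.0, 5),
}

_DEFAULT_CHEM_BASELINES = (1.0, -0.005, 0.1, -0.002)
_DEFAULT_THERM_BASELINES = (1.0, -0.0005, 0.1, -0.0002)
_SALT_I_GRID = np.array([0.041, 0.1, 0.2, 0.5, 1.0])


def _add_noise(rng, y: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.sigma == 0:
        return y
    scale = noise.sigma if noise.absolute else noise.sigma * (np.ptp(y) or 1.0)
    return y + rng.normal(0.0, scale, size=y.shape)


def generate(spec: ScenarioSpec):
    """Evaluate the forward model for ``spec`` and add seeded noise.

    Returns ``(dataset, truth)`` where ``dataset`` is the typed
    container the corresponding fit consumes and ``truth`` is the
    generating parameter record (spec.truth with defaults filled in).
    """
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind
    x = spec.grid.values()
    t = dict(spec.truth)

    if kind is ScenarioKind.chemical_curve:
        t.setdefault("baselines", _DEFAULT_CHEM_BASELINES)
        t.setdefault("temperature", DEFAULT_CONSTANTS.T_ref)
        y = two_state_signal(
            x, lfer_dG(x, t["m_DN"], t["urea50"]), t["baselines"], t["temperature"]
        )
        y = _add_noise(rng, y, spec.noise)
        curve = DenaturationCurve(
            perturbation=x, signal=y, probe=t.get("probe", Probe.CD222),
            mode="chemical", condition=Condition(label=t.get("label", "")),
        )
        return curve, t

    if kind is ScenarioKind.thermal_curve:
        t.setdefault("baselines", _DEFAULT_THERM_BASELINES)
        t.setdefault("n_residues", N_RESIDUES_DEFAULT)
        dCp = DEFAULT_CONSTANTS.dCp_per_residue * t["n_residues"]
        dG = gibbs_helmholtz_dG(x, t["dH_m"], t["T_m"], dCp)
        y = two_state_signal(x, dG, t["baselines"], x)
        y = _add_noise(rng, y, spec.noise)
        curve = DenaturationCurve(
            perturbation=x, signal=y, probe=t.get("probe", Probe.CD222),
            mode="thermal", condition=Condition(label=t.get("label", "")),
        )
        return curve, t

    if kind is ScenarioKind.folding_transient:
        t.setdefault("a", 1.0)
        t.setdefault("b", 0.0)
        t.setdefault("c", 0.2)
        y = exponential_with_drift(x, t["a"], t["k_obs"], t["b"], t["c"])
        y = y + spec.noise.drift_b * x
        y = _add_noise(rng, y, spec.noise)
        tr = KineticTransient(
            time=x, signal=y,
            meta=TransientMeta(
                experiment=ExperimentType.folding,
                final_urea=t.get("final_urea"), label=t.get("label", ""),
            ),
        )
        return tr, t

    if kind is ScenarioKind.association_transient:
        t.setdefault("S0", 1.0)
        t.setdefault("S_amp", -0.5)
        if "k_app" not in t:
            t["k_app"] = t["c_N"] * t["k_ass"]
        y = dimer_signal(x, t["S0"], t["S_amp"], t["k_app"])
        y = y + spec.noise.drift_b * x
        y = _add_noise(rng, y, spec.noise)
        tr = KineticTransient(
            time=x, signal=y,
            meta=TransientMeta(experiment=ExperimentType.association,
                               label=t.get("label", "")),
        )
        return tr, t

    if kind is ScenarioKind.dissociation_transient:
        t.setdefault("c", 0.5)
        t.setdefault("a", 0.5)
        y = t["c"] + t["a"] * (1.0 - np.exp(-t["k_diss"] * x))
        y = y + spec.noise.drift_b * x
        y = _add_noise(rng, y, spec.noise)
        tr = KineticTransient(
            time=x, signal=y,
            meta=TransientMeta(experiment=ExperimentType.dissociation,
                               label=t.get("label", "")),
        )
        return tr, t

    if kind is ScenarioKind.chevron:
        t.setdefault("temperature", DEFAULT_CONSTANTS.T_ref)
        logk = chevron_log10_k_obs(
            x, t["k_f"], t["m_f"], t["k_u"], t["m_u"], t["temperature"]
        )
        if spec.noise.sigma > 0:  # noise is absolute on log10 k_obs
            logk = logk + rng.normal(0.0, spec.noise.sigma, size=logk.shape)
        data = ChevronDataset(urea=x, k_obs=10.0**logk, temperature=t["temperature"])
        return data, t

    if kind is ScenarioKind.salt_series:
        return _generate_salt_series(spec, rng, t)

    raise InvalidInputError(f"unknown scenario kind {spec.kind!r}")


def _generate_salt_series(spec: ScenarioSpec, rng, t: dict):
    """Thermal (I, T_m, dH_m) table consistent with a known m_eq'.

    The underlying stability change ddG = m_eq' (sqrt(I) - sqrt(I_ref))
    is inverted through the Schellman relation to midpoint shifts,
    T_m(I) = T_m,ref + ddG * T_m,ref / dH_m. Noise sigma is absolute
    on ddG (kcal/mol).
    """
    I = spec.grid.values() if spec.grid.n != 5 else _SALT_I_GRID
    t.setdefault("dH_m", 54.8)
    t.setdefault("T_m_ref", 329.9)
    ddG = t["m_eq_prime"] * (np.sqrt(I) - np.sqrt(I[0]))
    if spec.noise.sigma > 0:
        ddG = ddG + rng.normal(0.0, spec.noise.sigma, size=ddG.shape)
    T_m = t["T_m_ref"] + ddG * t["T_m_ref"] / t["dH_m"]
    series = SaltSeries(
        ionic_strength=I, T_m=T_m, dH_m=np.full_like(I, t["dH_m"]),
        source="thermal", label=t.get("label", ""),
    )
    return series, t


def default_scenario(
    kind: ScenarioKind | str,
    label: str = "Lh",
    sigma: float = 0.0,
    seed: int = 0,
    probe: str = "CD222",
    **truth_overrides,
) -> ScenarioSpec:
    """Scenario for a homologue preset under the default designs."""
    kind = ScenarioKind(kind)
    p = preset(label)
    if kind is ScenarioKind.chemical_curve:
        m, u50 = p.equilibrium[probe]
        truth = {"m_DN": m, "urea50": u50, "probe": probe, "label": p.label}
    elif kind is ScenarioKind.thermal_curve:
        truth = {"dH_m": p.dH_m, "T_m": p.T_m, "n_residues": p.n_residues,
                 "label": p.label}
    elif kind is ScenarioKind.folding_transient:
        # observed rate at the final urea of a refolding mix (3 M),
        # evaluated from the preset chevron parameters
        final_urea = truth_overrides.pop("final_urea", 3.0)
        k_obs = float(
            10.0 ** chevron_log10_k_obs(final_urea, p.k_f, p.m_f, p.k_u, p.m_u)
        )
        truth = {"k_obs": k_obs, "final_urea": final_urea, "label": p.label}
    elif kind is ScenarioKind.association_transient:
        c_N = truth_overrides.pop("c_N", 100e-9)
        truth = {"k_ass": p.k_ass, "c_N": c_N, "label": p.label}
    elif kind is ScenarioKind.dissociation_transient:
        truth = {"k_diss": p.k_diss, "label": p.label}
    elif kind is ScenarioKind.chevron:
        truth = {"k_f": p.k_f, "m_f": p.m_f, "k_u": p.k_u, "m_u": p.m_u,
                 "label": p.label}
    elif kind is ScenarioKind.salt_series:
        truth = {"m_eq_prime": p.m_eq_prime, "dH_m": p.dH_m, "T_m_ref": p.T_m,
                 "label": p.label}
    else:  # pragma: no cover
        raise InvalidInputError(f"unknown scenario kind {kind!r}")
    truth.update(truth_overrides)
    absolute = kind in (ScenarioKind.chevron, ScenarioKind.salt_series)
    return ScenarioSpec(
        kind=kind, truth=truth, grid=_DEFAULT_GRIDS[kind],
        noise=NoiseSpec(sigma=sigma, absolute=absolute), seed=seed,
    )


def generate_salt_melt_curves(
    label: str = "Lh",
    I_grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
):
    """Full thermal melts at several ionic strengths for one homologue.

    Emulates the end-to-end salt experiment: the underlying m_eq' of the
    preset sets midpoint shifts via the inverse Schellman relation, and
    a complete melting curve is generated at each I (signal noise
    ``sigma`` as a fraction of amplitude). Returns
    ``(list of (I, DenaturationCurve), truth)``.
    """
    p = preset(label)
    I = _SALT_I_GRID if I_grid is None else np.asarray(I_grid, dtype=float)
    ddG = p.m_eq_prime * (np.sqrt(I) - np.sqrt(I[0]))
    T_ms = p.T_m + ddG * p.T_m / p.dH_m
    curves = []
    for j, (ionic, tm) in enumerate(zip(I, T_ms)):
        spec = ScenarioSpec(
            kind=ScenarioKind.thermal_curve,
            truth={"dH_m": p.dH_m, "T_m": float(tm), "n_residues": p.n_residues},
            grid=_DEFAULT_GRIDS[ScenarioKind.thermal_curve],
            noise=NoiseSpec(sigma=sigma),
            seed=seed + j,
        )
        curve, _ = generate(spec)
        curve = replace(curve, condition=Condition(ionic_strength=float(ionic),
                                                   label=p.label))
        curves.append((float(ionic), curve))
    truth = {"m_eq_prime": p.m_eq_prime, "dH_m": p.dH_m, "T_m_ref": p.T_m,
             "T_m_values": T_ms, "n_residues": p.n_residues}
    return curves, truth
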