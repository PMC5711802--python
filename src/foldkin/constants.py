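"""Physical constants and unit conventions.

Units used throughout the package: free energies in kcal/mol,
concentrations in M, temperatures in K, unimolecular rate constants in
1/s, bimolecular rate constants in 1/(M*s), m-values in kcal/(M*mol).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant, kcal mol^-1 K^-1.
R = 1.987e-3

#: Reference temperature for chemical denaturation and chevron fits, K.
T_REF = 298.0

#: Empirical heat-capacity increment of unfolding per residue,
#: kcal K^-1 mol^-1 (generic polypeptide value).
DCP_PER_RESIDUE = 0.014


@dataclass(frozen=True)
class Constants:
    """Overridable constants bundle used by the fitting routines."""

    R: float = R
    T_ref: float = T_REF
    dCp_per_residue: float = DCP_PER_RESIDUE

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T_ref <= 0:
            raise ValueError("R and T_ref must be positive")
        if self.dCp_per_residue < 0:
            raise ValueError("dCp_per_residue must be non-negative")

    @property
    def RT_ref(self) -> float:
        return self.R * self.T_ref


DEFAULT_CONSTANTS = Constants()
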