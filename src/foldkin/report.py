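"""Per-homologue report assembly.

Collects fitted results into the standard per-homologue summary rows
(equilibrium m / midpoint / dG per probe; thermal T_m / dH_m; chevron
rates and m-values with derived dG and beta_T; association k_ass /
k_diss / K_d) and renders them either as machine-readable JSON
(unrounded) or as a formatted text table (rounded: 2 decimals for dG,
m-values and K_d in nM; 1 decimal for T_m and dH_m). Rounding is
applied only at render time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .association import AssociationResult, DissociationResult, compute_Kd
from .equilibrium import ChemicalFitResult, ThermalFitResult
from .kinetics import ChevronFitResult

__all__ = ["HomologueReport", "build_report"]


@dataclass
class HomologueReport:
    """Structured per-homologue results; see :func:`build_report`."""

    rows: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return self.rows

    def to_json(self) -> str:
        return json.dumps(self.rows, indent=2)

    def render_text(self) -> str:
        lines = []
        for label, row in self.rows.items():
            lines.append(f"== {label} ==")
            for probe, eq in row.get("equilibrium", {}).items():
                lines.append(
                    f"  {probe}: m = {eq['m_DN']:.2f} kcal/M/mol, "
                    f"[urea]50 = {eq['urea50']:.2f} M, dG = {eq['dG_DN']:.2f} kcal/mol"
                )
            if "thermal" in row:
                th = row["thermal"]
                lines.append(
                    f"  melt: T_m = {th['T_m']:.1f} K, dH_m = {th['dH_m']:.1f} kcal/mol"
                )
            if "kinetics" in row:
                kin = row["kinetics"]
                lines.append(
                    f"  chevron: k_f = {kin['k_f']:.0f} /s, m_f = {kin['m_f']:.2f}, "
                    f"k_u = {kin['k_u']:.2f} /s, m_u = {kin['m_u']:.2f}, "
                    f"dG = {kin['dG_kin']:.2f} kcal/mol, beta_T = {kin['beta_T']:.2f}"
                )
            if "association" in row:
                a = row["association"]
                parts = []
                if a.get("k_ass") is not None:
                    parts.append(f"k_ass = {a['k_ass'] / 1e9:.2f}e9 /M/s")
                if a.get("k_diss") is not None:
                    parts.append(f"k_diss = {a['k_diss']:.2f} /s")
                if a.get("K_d_nM") is not None:
                    parts.append(f"K_d = {a['K_d_nM']:.2f} nM")
                lines.append("  association: " + ", ".join(parts))
        return "\n".join(lines)


def build_report(results: dict[str, dict]) -> HomologueReport:
    """Assemble fit results into a :class:`HomologueReport`.

    ``results`` maps homologue label to a dict with any of the keys
    ``equilibrium`` (probe -> ChemicalFitResult), ``thermal``
    (ThermalFitResult), ``chevron`` (ChevronFitResult), ``association``
    (AssociationResult), ``dissociation`` (DissociationResult). Empty
    sections are omitted from the report, and derived cells (dG, beta_T,
    K_d) are recomputed from the fitted cells.
    """
    if not results:
        raise ValueError("need at least one homologue's results")
    rows: dict[str, dict] = {}
    for label, sections in results.items():
        row: dict = {}
        eq_sec = sections.get("equilibrium") or {}
        if eq_sec:
            row["equilibrium"] = {}
            for probe, fit in eq_sec.items():
                assert isinstance(fit, ChemicalFitResult)
                row["equilibrium"][str(probe)] = {
                    "m_DN": fit.m_DN,
                    "urea50": fit.urea50,
                    "dG_DN": fit.dG_DN,
                    "dG_DN_err": fit.dG_DN_err,
                    "std_errors": fit.std_errors,
                }
        th = sections.get("thermal")
        if th is not None:
            assert isinstance(th, ThermalFitResult)
            row["thermal"] = {
                "T_m": th.T_m,
                "dH_m": th.dH_m,
                "dCp": th.dCp,
                "std_errors": th.std_errors,
            }
        kin = sections.get("chevron")
        if kin is not None:
            assert isinstance(kin, ChevronFitResult)
            row["kinetics"] = {
                "k_f": kin.k_f,
                "m_f": kin.m_TS_D,
                "k_u": kin.k_u,
                "m_u": kin.m_TS_N,
                "dG_kin": kin.dG_kin,
                "beta_T": kin.beta_T,
                "m_kin_sum": kin.m_kin_sum,
                "std_errors": kin.std_errors,
            }
        assoc = sections.get("association")
        diss = sections.get("dissociation")
        if assoc is not None or diss is not None:
            a: dict = {"k_ass": None, "k_diss": None, "K_d_nM": None}
            if assoc is not None:
                assert isinstance(assoc, AssociationResult)
                a["k_ass"] = assoc.k_ass
                a["k_ass_err"] = assoc.k_ass_err
            if diss is not None:
                assert isinstance(diss, DissociationResult)
                a["k_diss"] = diss.k_diss
                a["k_diss_err"] = diss.k_diss_err
            if assoc is not None and diss is not None:
                aff = compute_Kd(
                    diss.k_diss, assoc.k_ass, diss.k_diss_err, assoc.k_ass_err
                )
                a["K_d_nM"] = aff.K_d_nM
                a["K_d_nM_err"] = aff.std_error_nM
            row["association"] = a
        if row:
            rows[label] = row
    return HomologueReport(rows=rows)
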