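# foldkin

Folding thermodynamics and self-association kinetics of spidroin
N-terminal domains (NTDs) — and of small two-state proteins generally.

Spider dragline silk is spun from spidroin proteins whose N-terminal
domain acts as a pH-driven dimerization switch: monomeric under storage
conditions, it self-associates in the spinning duct and thereby links
spidroins into supermolecular fibres. Quantifying how conserved this
machinery is across species requires a consistent analysis of
equilibrium denaturation curves, stopped-flow folding kinetics,
dimerization/dissociation transients and the salt dependence of
stability. `foldkin` implements that entire analysis pipeline as
statsmodels-style model objects plus a thin `foldkin` command-line
tool, together with a seeded synthetic-data generator (raw spectroscopic
records for these domains are not publicly deposited) so every fit can
be validated by parameter recovery against known ground truth.

## Models

All free energies are in kcal·mol⁻¹, concentrations in M,
temperatures in K (gas constant R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹).

**Equilibrium two-state denaturation.** The observed signal is the
population-weighted average of two sloping baselines,

    S(P) = [αN + βN·P + (αD + βD·P)·exp(−ΔG(P)/RT)] / [1 + exp(−ΔG(P)/RT)]

with ΔG(P) given by the linear free-energy relationship
ΔG = m_D−N·([urea]₅₀ − [urea]) for chemical denaturation, or by the
Gibbs–Helmholtz expression
ΔG(T) = ΔH_m(1 − T/T_m) − ΔC_p[T_m − T + T·ln(T/T_m)] for thermal
melts (ΔC_p fixed at 0.014 kcal·K⁻¹·mol⁻¹ per residue). The stability
in water is ΔG_D−N = m_D−N·[urea]₅₀, with its standard error propagated
from the fitted covariance.

**Folding kinetics.** Stopped-flow transients are fitted as
S(t) = a·exp(−k_obs·t) + b·t + c; the denaturant dependence of k_obs is
the two-state chevron

    log k_obs = log[k_f·exp(−m_f·[urea]/RT) + k_u·exp(+m_u·[urea]/RT)]

fitted in log space. Derived: ΔG = −RT·ln(k_u/k_f) and the Tanford
value β_T = m_f/(m_f + m_u).

**Dimerization.** Association of two folded monomers (2N → N₂ with
d[N₂]/dt = k_ass[N]²) gives the hyperbolic signal
S(t) = S₀ + S·(k_app·t)/(1 + k_app·t) with k_app = c_N·k_ass;
chasing-dissociation transients are mono-exponential rises yielding
k_diss, and K_d = k_diss/k_ass.

**Electrostatics.** Debye–Hückel screening makes ΔG linear in √I; the
OLS slope m_eq′ (kcal·mol⁻¹·M⁻⁰·⁵) quantifies the electrostatic
contribution to stability. Thermal series are first converted to ΔΔG
via the Schellman relation ΔΔG = (ΔH_m/T_m)·ΔT_m.

## Worked example

Generate a noisy urea denaturation curve for the *L. hesperus* NTD
preset, fit it, and compare with a noise-free chevron fit of the same
homologue:

```python
import foldkin as fk
from foldkin import synthetic as syn

curve, truth = syn.generate(
    syn.default_scenario("chemical_curve", "Lh", sigma=0.01, seed=42))
fit = fk.fit_chemical_denaturation(curve)
print(fit.summary())

chev, _ = syn.generate(syn.default_scenario("chevron", "Lh"))
kin = fk.fit_chevron(chev)
print(fk.consistency_report_from_fits(fit, kin))
```

prints

```
Two-state chemical denaturation fit
===================================
n points: 33   residual norm: 0.03974
parameter           estimate     std err
m_DN                  1.6846      0.0465
urea50                 3.114       0.013
...
derived:
dG_DN                 5.2458       0.153

{'dG_eq': 5.245..., 'dG_kin': 4.548..., 'm_eq': 1.684..., 'm_kin_sum': 1.51,
 'rel_discrepancy_dG': 0.142..., 'rel_discrepancy_m': 0.109...,
 'two_state_consistent': True}
```

The fitted m-value (1.68 ± 0.05 kcal·M⁻¹·mol⁻¹) and midpoint
(3.11 ± 0.01 M) recover the generating truth (1.64, 3.09) within two
standard errors at 1% noise; the chevron gives
ΔG = −RT·ln(k_u/k_f) = 4.55 kcal·mol⁻¹ and β_T = 0.85, and the
equilibrium/kinetic discrepancies (14% and 11% here) are below the 20%
two-state consistency threshold.

The same fits are available from the shell:

```
foldkin simulate --kind chemical_curve --preset Lh --sigma 0.01 --seed 42 --out curve.csv
foldkin fit-equilibrium curve.csv --out fit.json
foldkin kd --k-ass 2.19e9 --k-diss 0.31     # -> K_d = 0.14 nM
```

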