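# Methods

This note records the models `foldkin` fits, the numerical choices
behind the fits, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several defensible
options existed.

## Two-state equilibrium model

Both chemical and thermal denaturation assume a two-state equilibrium
between native (N) and denatured (D) ensembles with no populated
intermediates. The observable is the population-weighted average of
two linearly sloping baselines; the native population is the logistic
function of ΔG/RT, evaluated through `scipy.special.expit` so the
model is finite for arbitrarily large |ΔG|/RT (tested to |ΔG/RT| =
500).

* Chemical mode: ΔG([urea]) = m_D−N·([urea]₅₀ − [urea]). The fit is
  parameterized directly in (m, [urea]₅₀) so that ΔG_D−N =
  m·[urea]₅₀ holds by construction and its standard error follows from
  the fitted covariance, σ²(ΔG) = ([urea]₅₀σ_m)² + (mσ₅₀)² +
  2m[urea]₅₀·cov. Both the covariance-aware and the independent-error
  forms are exposed, since published tables do not always state which
  was used. RT is evaluated at 298.0 K for isothermal titrations
  (override via the `temperature` argument).
* Thermal mode: ΔG(T) = ΔH_m(1 − T/T_m) − ΔC_p[T_m − T + T ln(T/T_m)]
  with ΔC_p held fixed at 0.014 kcal·K⁻¹·mol⁻¹ per residue. The
  residue count has no default — the per-residue increment is
  meaningless without it — so thermal fits require `n_residues`
  explicitly. The Boltzmann factor uses the running temperature of
  each point, not a reference temperature.

Free parameters are the two thermodynamic parameters plus four
baseline coefficients (6 total); curves must have ≥ 8 points.

### Initial guesses and multistart

The midpoint guess is the last crossing of the mid-signal level
scanning from the high-perturbation side (robust against a
cold-denaturation wing at the low-temperature end of a melt, which the
Gibbs–Helmholtz model predicts inside a 278–368 K scan whenever ΔC_p
is large); baselines come from linear fits to the outer 20% of points;
m (or ΔH_m) comes from the 10–90% width of the baseline-normalized
transition through ΔG/RT = ±ln 9. Fits run `scipy.optimize.curve_fit`
with physical bounds (T_m inside the scanned range, ΔH_m > 0, m > 0,
midpoint within ±50% of the data span) from the automatic guess plus
up to four restarts jittered ±20%; the lowest residual wins, and an
essentially perfect fit (residual < 10⁻⁹ of the signal norm) ends the
search early. Fits are unweighted unless a per-point sigma column is
present. A fit is rejected as degenerate when the two-state model does
not beat a straight line by at least 10 AIC units — a monotone,
transition-free curve fails rather than returning meaningless
parameters.

## Folding kinetics

Transients are fitted as a single exponential with linear drift
(photobleaching / sample diffusion); the initial rate guess comes from
a log-linear regression of |S − tail mean|. A warning (not an error)
is raised when the trace covers less than 3/k_obs. An optional
`dead_time` excludes early points.

The chevron is fitted in log₁₀(k_obs) space — the data span ~4 decades
and log residuals weight both limbs equally — and internally in
(log₁₀k_f, m_f, log₁₀k_u, m_u) coordinates to keep rates positive;
estimates and covariance are back-transformed by the delta method.
Starting values come from log-linear fits to each limb split at the
empirical minimum; data that do not bracket a minimum with ≥ 2 points
per limb raise an under-determined-fit error rather than extrapolating
a single limb. Derived quantities: ΔG = −RT ln(k_u/k_f) at the dataset
temperature (298 K default), β_T = m_f/(m_f+m_u), and the
equilibrium/kinetic consistency record flags a dataset two-state
consistent when both |ΔG_eq − ΔG_kin|/mean and |m_eq − (m_f+m_u)|/mean
are ≤ 20% (configurable).

## Dimerization kinetics

The association model treats 2N → N₂ as irreversible over the
observation window, giving the hyperbola S(t) = S₀ +
S·(k_app t)/(1 + k_app t). The package follows the convention
k_app = c_N·k_ass (the rate constant is defined through dimer
formation); the textbook monomer-loss convention (d[N]/dt =
−2k_ass[N]², k_app = 2c_N·k_ass) is available via
`stoichiometry_factor=2`, and the numerical ODE oracle in the test
suite integrates whichever convention is active. c_N is the
post-mixing monomer concentration; `c_N_from_premix` converts a premix
concentration and a volumetric mixing ratio such as 1:11. The
amplitude sign is unconstrained (tryptophan fluorescence is quenched
on dimerization, so association amplitudes are typically negative).
Dissociation (chasing) transients are mono-exponential rises; a fitted
amplitude below 10⁻⁶ of the signal scale signals that k_diss is
unidentifiable. K_d = k_diss/k_ass with the usual relative-error
propagation; c_N is treated as exact when propagating k_ass errors.

## Salt analysis

Debye–Hückel screening predicts stability linear in √I. The slope
m_eq′ comes from unweighted OLS (via `scipy.stats.linregress`; the
test suite checks it against the closed-form normal equations).
Thermal series are converted to ΔΔG with the Schellman relation. The
Schellman prefactor ΔH_m/T_m is anchored at the lowest-ionic-strength
melt of the series: the reference index only chooses which point is
ΔΔG = 0, so changing it shifts the regression intercept and leaves the
slope exactly unchanged. (Recomputing the prefactor from an arbitrary
reference would rescale the slope by the ratio of reference midpoint
temperatures — a ~1–2% artefact of bookkeeping, not physics.) A
`per_point_dH` option uses each melt's own enthalpy instead.

## Synthetic data

Generators evaluate exactly the forward models above on the default
experimental designs — urea titrations 0–8 M at 33 points, melts
278–368 K at 1 K steps, transients log-spaced 10⁻⁴–10 s at 500 points,
chevrons 0.5–8 M at 16 points, salt series at I ∈ {0.041, 0.1, 0.2,
0.5, 1.0} M — and add i.i.d. Gaussian noise, specified as a fraction
of the noise-free signal amplitude (default scenarios use 1%;
transient scenarios 1–2%), or absolute on log₁₀ k_obs for chevrons.
Optional linear drift can be added to transients. Each scenario owns
one integer seed (`numpy.random.default_rng`); identical
(scenario, seed) pairs are byte-identical, and no global random state
is touched.

Per-homologue presets carry the published central parameter values for
the four MaSp1 NTDs (Lh, Lg, Nc, Ea): equilibrium m and midpoint per
probe, T_m and ΔH_m, chevron rates and m-values, k_ass and k_diss, and
the salt slope m_eq′. Synthetic thermal scenarios use n_residues = 130
(the ~130-residue length scale of a spidroin NTD). The end-to-end salt
scenario inverts the Schellman relation to place melt midpoints
consistent with a known m_eq′ and generates a complete melt at each
ionic strength.

What the generator does **not** emulate: heteroscedastic or correlated
noise, photon shot noise, instrument dead-time distortion or mixing
artefacts beyond linear drift, thermal-scan hysteresis or
irreversibility, and the weak oligomeric contamination visible at
early times in real chasing experiments. Passing parameter-recovery
tests therefore demonstrates correctness and stability of the
estimators under the stated noise model, not robustness to every
instrumental pathology of real data.

## Problem sizes and numerical checks

The statistical validation uses 100 seeded replicates per scenario
(50–100 for chevrons) at 1–2% noise, asserting median parameter bias
below 5% and per-parameter ±2σ coverage ≥ 90%; the end-to-end salt
pipeline (five melts → Schellman → √I regression) must recover its
generating slope within 5% at 1% signal noise. Oracle equivalences are
held to tight tolerances: closed-form dimerization vs numerical ODE
integration to 10⁻⁶ relative, chevron evaluation vs brute-force branch
summation to 12 significant figures, OLS vs normal equations to 12
significant figures. The acceptance script reruns the full
generate→fit→derive pipeline for all four presets (~30 s on one CPU).

## Known limitations

Only two-state models are implemented — no intermediates, no global
multi-curve fits, no double exponentials, and no explicit treatment of
the labelled/unlabelled chasing equilibrium (reduced to a
mono-exponential). Standard errors are asymptotic (from the fit
covariance, residual-scaled when unweighted); replicate-scatter errors
are out of scope. The Debye–Hückel analysis is the empirical linear
model in √I, not an ion-cloud calculation. Thermal melts of marginally
stable proteins whose transition midpoint lies near the edge of the
scanned range are intrinsically harder to fit; the bounded multistart
makes failures rare but cannot make such data informative.
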