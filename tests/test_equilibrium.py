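"""Two-state equilibrium denaturation: signal model, fits, derived dG."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldkin as fk
from foldkin import synthetic as syn
from foldkin.datasets import DenaturationCurve
from foldkin.exceptions import FitFailureError, InvalidInputError, NumericalError

R, T_REF = fk.R, fk.T_REF


class TestTwoStateSignal:
    def test_equal_populations_at_midpoint(self):
        assert fk.two_state_signal(3.0, 0.0, (1, 0, 0, 0), 298.0) == pytest.approx(0.5)

    def test_fully_native_limit(self):
        s = fk.two_state_signal(0.0, 10.0, (1, 0, 0, 0), 298.0)
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluated_lfer_point(self):
        # direct scalar evaluation of the population-weighted baseline
        # average at P=2 with dG(P) = 5.07 - 1.64 P, frozen independently
        s = fk.two_state_signal(
            2.0, lambda u: 5.07 - 1.64 * u, (1, -0.01, 0.2, -0.005), 298.0
        )
        assert s == pytest.approx(0.9433461112923238, rel=1e-12)

    @pytest.mark.parametrize("dg_over_rt", [-500.0, 500.0])
    def test_no_overflow_at_extreme_stability(self, dg_over_rt):
        dg = dg_over_rt * R * 298.0
        s = fk.two_state_signal(1.0, dg, (1, 0, 0, 0), 298.0)
        assert np.isfinite(s)
        assert s == pytest.approx(1.0 if dg > 0 else 0.0, abs=1e-12)

    def test_nonfinite_dG_rejected(self):
        with pytest.raises(InvalidInputError):
            fk.two_state_signal(1.0, np.nan, (1, 0, 0, 0), 298.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        m=st.floats(0.3, 5.0),
        u50=st.floats(0.5, 8.0),
        T=st.floats(273.0, 373.0),
    )
    def test_midpoint_property_flat_baselines(self, m, u50, T):
        # S = 0.5 exactly where dG = 0, for any LFER parameter set
        s = fk.two_state_signal(u50, fk.lfer_dG(u50, m, u50), (1, 0, 0, 0), T)
        assert s == pytest.approx(0.5, abs=1e-12)


class TestChemicalFit:
    def test_recovers_lh_parameters_noise_free(self, lh_chemical_curve, sig_figs):
        curve, truth = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        sig_figs(fit.m_DN, truth["m_DN"], 4)
        sig_figs(fit.urea50, truth["urea50"], 4)

    def test_nc_stability_after_rounding(self):
        spec = syn.default_scenario("chemical_curve", "Nc")
        curve, _ = syn.generate(spec)
        fit = fk.fit_chemical_denaturation(curve)
        assert round(fit.dG_DN, 2) == 3.48

    @pytest.mark.parametrize("m,u50", [(0.5, 1.0), (1.5, 3.5), (3.0, 6.0)])
    def test_lfer_consistency_across_parameter_space(self, m, u50, sig_figs):
        spec = syn.default_scenario("chemical_curve", "Lh")
        spec = syn.ScenarioSpec(
            kind=spec.kind, truth={"m_DN": m, "urea50": u50}, grid=spec.grid
        )
        curve, _ = syn.generate(spec)
        fit = fk.fit_chemical_denaturation(curve)
        sig_figs(fit.m_DN, m, 4)
        sig_figs(fit.urea50, u50, 4)

    def test_noisy_fit_within_three_standard_errors(self):
        spec = syn.default_scenario("chemical_curve", "Lh", sigma=0.01, seed=42)
        curve, truth = syn.generate(spec)
        fit = fk.fit_chemical_denaturation(curve)
        assert abs(fit.m_DN - truth["m_DN"]) <= 3 * fit.bse["m_DN"]
        assert abs(fit.urea50 - truth["urea50"]) <= 3 * fit.bse["urea50"]

    def test_dG_construction_identity(self, lh_chemical_curve):
        curve, _ = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        assert fit.dG_DN == fit.m_DN * fit.urea50

    def test_degenerate_monotone_curve_rejected(self):
        u = np.linspace(0, 8, 33)
        rng = np.random.default_rng(0)
        curve = DenaturationCurve(
            perturbation=u, signal=1.0 - 0.05 * u + rng.normal(0, 0.002, u.size),
            mode="chemical",
        )
        with pytest.raises(FitFailureError):
            fk.fit_chemical_denaturation(curve)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            DenaturationCurve(
                perturbation=np.linspace(0, 8, 5),
                signal=np.ones(5),
                mode="chemical",
            )


class TestThermalFit:
    def test_recovers_melt_parameters_noise_free(self, sig_figs):
        spec = syn.default_scenario("thermal_curve", "Lh")
        curve, truth = syn.generate(spec)
        fit = fk.fit_thermal_denaturation(curve, truth["n_residues"])
        sig_figs(fit.dH_m, 54.8, 3)
        sig_figs(fit.T_m, 329.9, 3)
        assert fit.dCp == pytest.approx(0.014 * truth["n_residues"])

    def test_dG_is_zero_at_fitted_midpoint(self):
        spec = syn.default_scenario("thermal_curve", "Ea")
        curve, truth = syn.generate(spec)
        fit = fk.fit_thermal_denaturation(curve, truth["n_residues"])
        assert fit.dG(fit.T_m) == pytest.approx(0.0, abs=1e-10)

    def test_noisy_ea_melt_within_three_standard_errors(self):
        spec = syn.default_scenario("thermal_curve", "Ea", sigma=0.01, seed=7)
        curve, truth = syn.generate(spec)
        fit = fk.fit_thermal_denaturation(curve, truth["n_residues"])
        assert abs(fit.dH_m - 67.5) <= 3 * fit.bse["dH_m"]
        assert abs(fit.T_m - 337.0) <= 3 * fit.bse["T_m"]

    def test_zero_dCp_reduces_to_vant_hoff(self):
        T = np.linspace(280, 360, 50)
        full = fk.gibbs_helmholtz_dG(T, 60.0, 330.0, 0.0)
        vant_hoff = 60.0 * (1 - T / 330.0)
        np.testing.assert_allclose(full, vant_hoff, rtol=1e-14)

    def test_requires_positive_residue_count(self):
        spec = syn.default_scenario("thermal_curve", "Lh")
        curve, _ = syn.generate(spec)
        with pytest.raises(InvalidInputError):
            fk.fit_thermal_denaturation(curve, 0)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "m,u50,expected",
        [(1.64, 3.09, 5.07), (1.67, 2.18, 3.64), (0.0, 4.2, 0.0)],
    )
    def test_dG_from_m_and_midpoint(self, m, u50, expected):
        assert round(fk.dG_from_m_and_midpoint(m, u50), 2) == expected

    def test_error_propagation_independent_form(self):
        # sqrt((3.09*0.04)^2 + (1.64*0.01)^2), frozen by hand
        err = fk.propagate_dG_error(1.64, 0.04, 3.09, 0.01)
        assert err == pytest.approx(0.12468327875060072, rel=1e-12)

    def test_error_propagation_zero_inputs(self):
        assert fk.propagate_dG_error(1.5, 0.0, 3.0, 0.0) == 0.0

    def test_positive_covariance_increases_error(self):
        indep = fk.propagate_dG_error(1.64, 0.04, 3.09, 0.01)
        with_cov = fk.propagate_dG_error(1.64, 0.04, 3.09, 0.01, cov_m_mid=1e-4)
        assert indep <= with_cov

    def test_negative_variance_raises(self):
        with pytest.raises(NumericalError):
            fk.propagate_dG_error(1.0, 0.01, 1.0, 0.01, cov_m_mid=-1.0)

    def test_schellman_no_shift(self):
        assert fk.schellman_ddG(54.8, 329.9, 0.0) == 0.0

    def test_schellman_hand_value(self):
        assert fk.schellman_ddG(54.8, 329.9, 5.0) == pytest.approx(
            0.8305547135495605, rel=1e-12
        )

    @settings(derandomize=True, max_examples=30)
    @given(dH=st.floats(10.0, 100.0), Tm=st.floats(300.0, 360.0),
           dT=st.floats(-10.0, 10.0))
    def test_schellman_sign_follows_shift(self, dH, Tm, dT):
        assert math.copysign(1.0, fk.schellman_ddG(dH, Tm, dT)) == math.copysign(
            1.0, dT
        ) or dT == 0


class TestFoldedFraction:
    def test_midpoint_maps_to_half(self, lh_chemical_curve):
        curve, truth = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        f = fk.folded_fraction(curve, fit)
        at_mid = np.interp(truth["urea50"], curve.perturbation, f)
        assert at_mid == pytest.approx(0.5, abs=1e-3)

    def test_matches_two_state_population_exactly(self, lh_chemical_curve):
        curve, truth = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        f = fk.folded_fraction(curve, fit)
        from scipy.special import expit

        dg = fk.lfer_dG(curve.perturbation, truth["m_DN"], truth["urea50"])
        np.testing.assert_allclose(f, expit(dg / (R * T_REF)), atol=1e-8)

    def test_native_limit_maps_to_one(self):
        # a strongly stable curve (dG0 = 18 kcal/mol) is fully native at
        # zero denaturant
        spec = syn.default_scenario("chemical_curve", "Lh")
        spec = syn.ScenarioSpec(
            kind=spec.kind, truth={"m_DN": 3.0, "urea50": 6.0}, grid=spec.grid
        )
        curve, _ = syn.generate(spec)
        fit = fk.fit_chemical_denaturation(curve)
        f = fk.folded_fraction(curve, fit)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_normalized_refit_round_trip(self, lh_chemical_curve, sig_figs):
        curve, truth = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        normalized = curve.with_signal(fk.folded_fraction(curve, fit))
        refit = fk.fit_chemical_denaturation(normalized)
        sig_figs(refit.m_DN, truth["m_DN"], 4)
        sig_figs(refit.urea50, truth["urea50"], 4)

    def test_coincident_baselines_rejected(self, lh_chemical_curve):
        from dataclasses import replace

        curve, _ = lh_chemical_curve
        fit = fk.fit_chemical_denaturation(curve)
        bad = replace(fit, popt=np.array([1.6, 3.1, 1.0, 0.0, 1.0, 0.0]))
        with pytest.raises(fk.DegenerateNormalizationError):
            fk.folded_fraction(curve, bad)


class TestStatisticalRecovery:
    def test_mean_recovery_and_coverage_over_replicates(self):
        """100 noisy replicates: mean within 1% of truth, 2-sigma
        coverage of each parameter at or above 90%."""
        ms, mids, cov_m, cov_mid = [], [], 0, 0
        for i in range(100):
            spec = syn.default_scenario("chemical_curve", "Lh", sigma=0.01,
                                        seed=1000 + i)
            curve, truth = syn.generate(spec)
            fit = fk.fit_chemical_denaturation(curve)
            ms.append(fit.m_DN)
            mids.append(fit.urea50)
            cov_m += abs(fit.m_DN - truth["m_DN"]) <= 2 * fit.bse["m_DN"]
            cov_mid += abs(fit.urea50 - truth["urea50"]) <= 2 * fit.bse["urea50"]
        assert abs(np.mean(ms) - 1.64) / 1.64 < 0.01
        assert abs(np.mean(mids) - 3.09) / 3.09 < 0.01
        assert cov_m >= 90
        assert cov_mid >= 90
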