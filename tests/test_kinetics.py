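"""Stopped-flow transients, chevron analysis, derived kinetic quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldkin as fk
from foldkin import synthetic as syn
from foldkin.datasets import ChevronDataset, KineticTransient
from foldkin.exceptions import InvalidInputError, UnderdeterminedFitError

R, T_REF = fk.R, fk.T_REF
RT = R * T_REF


class TestTransientFit:
    def test_exact_recovery_noise_free(self, sig_figs):
        t = np.geomspace(1e-4, 0.2, 200)
        tr = KineticTransient(
            time=t, signal=fk.exponential_with_drift(t, 1.0, 100.0, 0.0, 0.2)
        )
        fit = fk.fit_exponential_with_drift(tr)
        sig_figs(fit.k_obs, 100.0, 6)
        sig_figs(fit.a, 1.0, 6)
        sig_figs(fit.c, 0.2, 6)

    def test_photobleaching_drift_recovered(self, sig_figs):
        t = np.geomspace(1e-4, 1.0, 300)
        tr = KineticTransient(
            time=t, signal=fk.exponential_with_drift(t, 1.0, 50.0, -0.01, 0.2)
        )
        fit = fk.fit_exponential_with_drift(tr)
        for got, want in zip(fit.popt, (1.0, 50.0, -0.01, 0.2)):
            sig_figs(got, want, 4)

    def test_noisy_rate_within_three_standard_errors(self):
        spec = syn.default_scenario("folding_transient", "Lh", sigma=0.02, seed=5)
        spec = syn.ScenarioSpec(
            kind=spec.kind, truth={"k_obs": 500.0}, grid=spec.grid,
            noise=spec.noise, seed=5,
        )
        tr, truth = syn.generate(spec)
        fit = fk.fit_exponential_with_drift(tr)
        assert abs(fit.k_obs - 500.0) <= 3 * fit.bse["k_obs"]

    def test_short_trace_warns(self):
        t = np.linspace(0, 0.01, 30)
        tr = KineticTransient(
            time=t, signal=fk.exponential_with_drift(t, 1.0, 10.0, 0.0, 0.0)
        )
        with pytest.warns(UserWarning, match="3/k_obs"):
            fk.fit_exponential_with_drift(tr)


class TestChevronModel:
    def test_model_at_zero_urea_is_rate_sum(self):
        logk = fk.chevron_log10_k_obs(0.0, 10123.0, 1.29, 4.67, 0.22)
        assert 10.0**logk == pytest.approx(10123.0 + 4.67, rel=1e-12)

    def test_brute_force_branch_summation_oracle(self):
        # independent evaluation: plain sum of the two exponential branches
        u = np.linspace(0, 8, 33)
        for k_f, m_f, k_u, m_u in [
            (10123.0, 1.29, 4.67, 0.22),
            (3652.0, 1.39, 12.16, 0.28),
            (1e6, 2.5, 1e-3, 0.05),
        ]:
            brute = np.log10(
                k_f * np.exp(-m_f * u / RT) + k_u * np.exp(m_u * u / RT)
            )
            got = fk.chevron_log10_k_obs(u, k_f, m_f, k_u, m_u)
            np.testing.assert_allclose(got, brute, rtol=1e-12)

    def test_recovers_lh_chevron_noise_free(self, lh_chevron, sig_figs):
        data, truth = lh_chevron
        fit = fk.fit_chevron(data)
        sig_figs(fit.k_f, truth["k_f"], 3)
        sig_figs(fit.k_u, truth["k_u"], 3)
        sig_figs(fit.m_TS_D, truth["m_f"], 3)
        sig_figs(fit.m_TS_N, truth["m_u"], 3)

    def test_high_urea_limb_slope_matches_analytic_limit(self, lh_chevron):
        data, truth = lh_chevron
        fit = fk.fit_chevron(data)
        u = np.linspace(8.0, 10.0, 50)  # far above the midpoint
        slope = np.polyfit(u, fit.predict_log10(u), 1)[0]
        assert slope == pytest.approx(truth["m_u"] / (RT * math.log(10)), rel=0.01)

    def test_single_limb_data_rejected(self):
        u = np.linspace(4, 8, 8)
        k = 4.67 * np.exp(0.22 * u / RT)
        with pytest.raises(UnderdeterminedFitError):
            fk.fit_chevron(ChevronDataset(urea=u, k_obs=k))

    def test_fitted_chevron_is_convex_with_unique_minimum(self, lh_chevron):
        data, _ = lh_chevron
        fit = fk.fit_chevron(data)
        u = np.linspace(0, 8, 200)
        y = fit.predict_log10(u)
        second = np.diff(y, 2)
        assert np.all(second > -1e-12)
        assert 0 < int(np.argmin(y)) < len(u) - 1

    def test_median_bias_under_log_noise(self):
        """50 replicates at sigma_log = 0.02: median |bias| < 5% per
        parameter."""
        truth = np.array([10123.0, 1.29, 4.67, 0.22])
        biases = []
        for i in range(50):
            spec = syn.default_scenario("chevron", "Lh", sigma=0.02, seed=2000 + i)
            data, _ = syn.generate(spec)
            fit = fk.fit_chevron(data)
            got = np.array([fit.k_f, fit.m_TS_D, fit.k_u, fit.m_TS_N])
            biases.append((got - truth) / truth)
        med = np.abs(np.median(np.array(biases), axis=0))
        assert np.all(med < 0.05)


class TestDerivedKinetics:
    @pytest.mark.parametrize(
        "k_f,k_u,expected",
        [(10123.0, 4.67, 4.55), (13257.0, 3.28, 4.92)],
    )
    def test_dG_from_rates_reproduces_tables(self, k_f, k_u, expected):
        assert round(fk.dG_from_rates(k_f, k_u, 298.0), 2) == expected

    def test_dG_zero_for_equal_rates(self):
        assert fk.dG_from_rates(7.0, 7.0, 298.0) == 0.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            fk.dG_from_rates(0.0, 1.0)

    @pytest.mark.parametrize(
        "m_f,m_u,expected", [(1.29, 0.22, 0.85), (1.39, 0.28, 0.83)]
    )
    def test_tanford_beta_reproduces_tables(self, m_f, m_u, expected):
        assert round(fk.tanford_beta(m_f, m_u), 2) == expected

    def test_fully_native_like_transition_state(self):
        assert fk.tanford_beta(1.3, 0.0) == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(k_f=st.floats(1e2, 1e5), k_u=st.floats(0.1, 50.0),
           c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, k_f, k_u, c):
        base = fk.dG_from_rates(k_f, k_u)
        scaled = fk.dG_from_rates(c * k_f, c * k_u)
        assert scaled == pytest.approx(base, abs=1e-9)
        assert fk.tanford_beta(c * 1.29, c * 0.22) == pytest.approx(
            fk.tanford_beta(1.29, 0.22), rel=1e-12
        )


class TestConsistency:
    def test_lh_published_m_values_consistent(self):
        rec = fk.consistency_report(5.07, 1.64, 4.55, 1.51)
        assert rec["rel_discrepancy_m"] == pytest.approx(0.08254, abs=1e-4)
        assert rec["two_state_consistent"]

    def test_nc_published_dG_consistent(self):
        rec = fk.consistency_report(3.48, 1.59, 3.38, 1.67)
        assert rec["rel_discrepancy_dG"] == pytest.approx(0.029155, abs=1e-4)
        assert rec["two_state_consistent"]

    def test_identical_parameters_zero_discrepancy(self):
        rec = fk.consistency_report(4.5, 1.5, 4.5, 1.5)
        assert rec["rel_discrepancy_dG"] == 0.0
        assert rec["rel_discrepancy_m"] == 0.0
        assert rec["two_state_consistent"]
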