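"""Unit and property tests for the kinetic model layer."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fermkin import (
    CultureState,
    KineticParameters,
    TimeCourse,
    logistic_biomass_integral,
    logistic_closed_form,
    model_rhs,
    specific_growth_rate,
)

BBF002 = KineticParameters(1.617, 19.891, 0.45, 0.033, 0.055, 0.020)

params_strategy = st.builds(
    KineticParameters,
    mu_max=st.floats(0.1, 5.0),
    C_Xm=st.floats(1.0, 60.0),
    Y_XS=st.floats(0.1, 1.0),
    m_S=st.floats(0.0, 0.5),
    alpha=st.floats(0.0, 1.0),
    beta=st.floats(0.0, 0.5),
)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_max": 0.0, "C_Xm": 10.0},
            {"mu_max": 1.0, "C_Xm": -1.0},
            {"mu_max": 1.0, "C_Xm": 10.0, "Y_XS": 0.0},
            {"mu_max": 1.0, "C_Xm": 10.0, "Y_XS": 1.5},
            {"mu_max": 1.0, "C_Xm": 10.0, "m_S": -0.1},
        ],
    )
    def test_parameter_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParameters(**kwargs)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            CultureState(-0.1, 40.0, 0.0)

    def test_timecourse_requires_strictly_increasing_times(self):
        with pytest.raises(ValueError):
            TimeCourse([0.0, 1.0, 1.0], [1, 2, 3], [4, 3, 2], [0, 0, 0])

    def test_timecourse_replicates_may_share_times(self):
        tc = TimeCourse(
            [0.0, 0.0, 1.0, 1.0], [1, 1.2, 2, 2.1], [40, 39, 30, 31], [0, 0, 0.1, 0.2],
            replicate=[0, 1, 0, 1],
        )
        assert len(tc) == 4 and tc.n_times == 2


class TestSpecificGrowthRate:
    def test_zero_density_gives_mu_max(self):
        assert specific_growth_rate(0.0, BBF002) == pytest.approx(BBF002.mu_max)

    def test_carrying_capacity_gives_zero(self):
        assert specific_growth_rate(BBF002.C_Xm, BBF002) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value_at_one_gram_per_liter(self):
        # 1.617 * (1 - 1/19.891)
        assert specific_growth_rate(1.0, BBF002) == pytest.approx(1.5357, abs=5e-5)

    def test_overshoot_goes_negative_not_clamped(self):
        assert specific_growth_rate(2 * BBF002.C_Xm, BBF002) < 0

    @given(params=params_strategy, frac=st.floats(0.0, 2.0))
    def test_affine_in_biomass(self, params, frac):
        c = frac * params.C_Xm
        expected = params.mu_max - (params.mu_max / params.C_Xm) * c
        assert specific_growth_rate(c, params) == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestModelRhs:
    def test_no_biomass_no_fluxes(self):
        assert model_rhs((0.0, 40.0, 0.0), BBF002) == (0.0, 0.0, 0.0)

    def test_hand_values_exponential_phase(self):
        dX, dS, dP = model_rhs(CultureState(1.0, 40.0, 0.0), BBF002)
        assert dX == pytest.approx(1.53571, abs=1e-5)
        assert dS == pytest.approx(-1.53571 / 0.45 - 0.033, abs=1e-4)
        assert dP == pytest.approx(0.10446, abs=1e-5)

    def test_stationary_phase_maintenance_and_beta_only(self):
        dX, dS, dP = model_rhs((BBF002.C_Xm, 40.0, 0.0), BBF002)
        assert dX == pytest.approx(0.0, abs=1e-12)
        assert dS == pytest.approx(-BBF002.m_S * BBF002.C_Xm)
        assert dP == pytest.approx(BBF002.beta * BBF002.C_Xm)

    def test_substrate_clamp_zeroes_consumption_at_exhaustion(self):
        _, dS, _ = model_rhs((5.0, 0.0, 0.5), BBF002)
        assert dS == 0.0

    @given(params=params_strategy, c_x=st.floats(0.01, 60.0))
    def test_product_conserved_when_both_coefficients_zero(self, params, c_x):
        p = params.replace(alpha=0.0, beta=0.0)
        _, _, dP = model_rhs((c_x, 10.0, 1.0), p)
        assert dP == 0.0


class TestLogisticClosedForm:
    def test_initial_condition(self):
        assert logistic_closed_form(0.0, 0.6, BBF002) == pytest.approx(0.6)

    def test_asymptote(self):
        assert logistic_closed_form(50.0, 0.6, BBF002) == pytest.approx(
            BBF002.C_Xm, abs=1e-6
        )

    def test_hand_value_day_two(self):
        # C_Xm X0 e^{mu t} / (C_Xm - X0 + X0 e^{mu t}) at t=2, X0=0.6
        e = np.exp(BBF002.mu_max * 2.0)
        expected = BBF002.C_Xm * 0.6 * e / (BBF002.C_Xm - 0.6 + 0.6 * e)
        assert expected == pytest.approx(8.775, abs=5e-3)
        assert logistic_closed_form(2.0, 0.6, BBF002) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inoculum_rejected(self):
        with pytest.raises(ValueError):
            logistic_closed_form(1.0, 0.0, BBF002)

    @settings(max_examples=50)
    @given(params=params_strategy, x0_frac=st.floats(0.01, 0.99))
    def test_strictly_increasing_and_bounded_below_capacity(self, params, x0_frac):
        x0 = x0_frac * params.C_Xm
        t = np.linspace(0, 20, 64)
        x = logistic_closed_form(t, x0, params)
        d = np.diff(x)
        assert np.all(d >= 0)
        # strictly increasing until the trajectory saturates at double precision
        unsaturated = x[1:] < params.C_Xm * (1 - 1e-9)
        assert np.all(d[unsaturated] > 0)
        assert np.all(x <= params.C_Xm * (1 + 1e-12))

    def test_integral_matches_quadrature(self):
        got = logistic_biomass_integral(3.0, 0.6, BBF002)
        ref, err = quad(lambda t: logistic_closed_form(t, 0.6, BBF002), 0, 3.0)
        assert got == pytest.approx(ref, rel=1e-8)

    def test_substrate_balance_without_maintenance(self):
        """With m_S = 0, consumed substrate equals delta-biomass / Y_XS."""
        p = BBF002.replace(m_S=0.0)
        t = 2.5
        dx = logistic_closed_form(t, 0.6, p) - 0.6
        consumed, _ = quad(
            lambda tau: (p.mu_max * (1 - logistic_closed_form(tau, 0.6, p) / p.C_Xm))
            * logistic_closed_form(tau, 0.6, p)
            / p.Y_XS,
            0,
            t,
        )
        assert consumed == pytest.approx(dx / p.Y_XS, rel=1e-7)
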