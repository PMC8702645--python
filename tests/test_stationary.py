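import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from qifbalance import ModelParams
from qifbalance.mean_field import (
    MacroState,
    asymptotic_effective_currents,
    current_fluctuations,
    effective_currents,
    mf_derivative,
    rate_expansion,
    stationary_state,
)

# random-but-feasible parameter sets for property tests
feasible_params = st.builds(
    ModelParams,
    g0_ee=st.floats(0.1, 0.5),
    g0_ei=st.floats(0.8, 1.2),
    g0_ie=st.floats(0.2, 0.6),
    g0_ii=st.floats(0.7, 1.1),
    I0_e=st.floats(0.05, 1.0),
    K=st.floats(400.0, 4000.0),
    delta0_ee=st.floats(0.0, 3.0),
    delta0_ii=st.floats(0.0, 2.0),
).filter(lambda p: p.is_balance_feasible())


class TestDerivative:
    def test_zero_rate_manifold_is_invariant(self, async_params):
        d = mf_derivative(MacroState(0.0, -0.3, 0.0, 0.2), async_params)
        assert d.R_e == 0.0 and d.R_i == 0.0

    def test_rate_equation_bracket_vanishes_at_stationary_potential(self, async_params):
        p = async_params
        d = mf_derivative(MacroState(0.7, p.v_bar_e, 0.1, 0.4), p)
        assert d.R_e == pytest.approx(0.0, abs=1e-15)

    def test_nonfinite_state_rejected(self, async_params):
        with pytest.raises(ValueError, match="non-finite"):
            mf_derivative(MacroState(np.nan, 0.0, 0.0, 0.0), async_params)

    def test_derivative_vanishes_at_exact_fixed_point(self, async_params):
        fp = stationary_state(async_params, "exact")
        d = mf_derivative(fp.as_state(), async_params).as_array()
        assert np.max(np.abs(d)) < 1e-10


class TestExpansion:
    def test_first_order_balance_identity(self, async_params):
        """tau*(g_ee R1_e - g_ei R1_i) must equal (pi R0_e tau)^2 - Vbar_e^2.

        This is the order-eps matching condition of the stationary system
        and an independent check of the recursion's sign conventions.
        """
        p = async_params
        exp = rate_expansion(p, 1)
        tau = p.tau_m_e
        lhs_e = tau * (p.g0_ee * exp.coeffs_e[1] - p.g0_ei * exp.coeffs_i[1])
        rhs_e = (np.pi * exp.coeffs_e[0] * tau) ** 2 - p.v_bar_e**2
        lhs_i = tau * (p.g0_ie * exp.coeffs_e[1] - p.g0_ii * exp.coeffs_i[1])
        rhs_i = (np.pi * exp.coeffs_i[0] * tau) ** 2 - p.v_bar_i**2
        assert lhs_e == pytest.approx(rhs_e, abs=1e-12)
        assert lhs_i == pytest.approx(rhs_i, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(feasible_params)
    def test_first_order_identity_holds_generically(self, p):
        exp = rate_expansion(p, 1)
        tau = p.tau_m_e
        lhs = tau * (p.g0_ee * exp.coeffs_e[1] - p.g0_ei * exp.coeffs_i[1])
        rhs = (np.pi * exp.coeffs_e[0] * tau) ** 2 - p.v_bar_e**2
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_partial_sums_strictly_improve_with_order(self, async_params):
        p = async_params.replace(K=1.0e4)
        exact = stationary_state(p, "exact")
        exp = rate_expansion(p, 2)
        errs = [
            abs(exp.partial_sum(m)[0] - exact.R_bar_e) for m in range(3)
        ]
        assert errs[2] < errs[1] < errs[0]

    def test_truncation_error_scales_with_eps_power(self, async_params):
        """The order-m truncation error scales as eps^(m+1): going from
        K = 1e4 to 1e6 (eps drops 10x) shrinks the order-0 error ~10x and
        the order-1 error ~100x."""
        errs = {}
        for K in (1.0e4, 1.0e6):
            p = async_params.replace(K=K)
            exact = stationary_state(p, "exact").R_bar_e
            exp = rate_expansion(p, 1)
            errs[K] = [abs(exp.partial_sum(m)[0] - exact) for m in range(2)]
        ratio0 = errs[1.0e6][0] / errs[1.0e4][0]
        ratio1 = errs[1.0e6][1] / errs[1.0e4][1]
        assert ratio0 == pytest.approx(0.1, rel=0.5)
        # the order-1 error gains at least one further power of eps (the
        # higher-order coefficients grow, so the gain can exceed eps^2)
        assert ratio1 <= 0.02

    def test_degenerate_coupling_matrix_raises(self):
        p = ModelParams(g0_ee=0.5, g0_ei=1.0, g0_ie=0.5, g0_ii=1.0, I0_e=0.5, I0_i=0.2)
        with pytest.raises(ValueError, match="degenerate"):
            rate_expansion(p, 1)


class TestStationaryState:
    def test_exact_solve_residual_below_tolerance(self, async_params):
        fp = stationary_state(async_params, "exact")
        assert fp.residual < 1e-12
        assert fp.R_bar_e >= 0 and fp.R_bar_i >= 0

    def test_potentials_follow_heterogeneity(self, async_params):
        fp = stationary_state(async_params, "exact")
        assert fp.V_bar_e == pytest.approx(async_params.v_bar_e)
        assert fp.V_bar_i == pytest.approx(async_params.v_bar_i)

    def test_balance_warning_flag(self):
        p = ModelParams(I0_e=0.2, I0_i=0.2 / 0.95, K=100.0)
        fp = stationary_state(p, "exact")
        assert fp.balance_warning

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(feasible_params)
    def test_exact_fixed_point_kills_the_flow(self, p):
        # at small K the balanced branch can be annihilated even for
        # feasible couplings; such draws carry no information here
        try:
            fp = stationary_state(p, "exact")
        except ValueError:
            assume(False)
        d = mf_derivative(fp.as_state(), p).as_array()
        assert np.max(np.abs(d)) < 1e-10


class TestEffectiveCurrents:
    def test_decoupled_limit_reduces_to_external_drive(self):
        p = ModelParams(g0_ee=1e-12, g0_ei=1e-12, g0_ie=1e-12, g0_ii=1e-12)
        ie, ii = effective_currents(p, 5e-3, 1e-2)
        assert ie == pytest.approx(p.sqrt_K * p.I0_e, rel=1e-8)
        assert ii == pytest.approx(p.sqrt_K * p.I0_i, rel=1e-8)

    def test_asymptotic_currents_equal_rate_identity(self, async_params):
        """Ia_a = (pi R0_a tau)^2 - Vbar_a^2 (order-eps matching)."""
        p = async_params
        ia_e, ia_i = asymptotic_effective_currents(p)
        exp = rate_expansion(p, 0)
        tau = p.tau_m_e
        assert ia_e == pytest.approx((np.pi * exp.coeffs_e[0] * tau) ** 2 - p.v_bar_e**2, abs=1e-12)
        assert ia_i == pytest.approx((np.pi * exp.coeffs_i[0] * tau) ** 2 - p.v_bar_i**2, abs=1e-12)

    def test_finite_K_currents_tend_to_asymptotic_values(self, async_params):
        """Effective currents at the order-2 rates approach Ia as O(eps).

        (At the exactly-truncated order-1 rates the sqrt(K) prefactor
        cancels the balance term algebraically, so the order-2 rates are
        the first ones showing the finite-K approach.)
        """
        p0 = async_params
        ia = np.array(asymptotic_effective_currents(p0))
        gaps = []
        for K in (1e4, 1e6, 1e8):
            p = p0.replace(K=K)
            exp = rate_expansion(p, 2)
            r_e, r_i = exp.partial_sum(2)
            gaps.append(np.abs(np.array(effective_currents(p, r_e, r_i)) - ia).max())
        assert gaps[1] < 0.2 * gaps[0]
        assert gaps[2] < 0.2 * gaps[1]

    def test_negative_rates_rejected(self, async_params):
        with pytest.raises(ValueError):
            effective_currents(async_params, -1e-3, 1e-3)


class TestCurrentFluctuations:
    def test_zero_rates_give_zero_fluctuations(self, async_params):
        assert current_fluctuations(async_params, 0.0, 0.0) == (0.0, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        feasible_params,
        st.floats(1e-4, 0.05),
        st.floats(1e-4, 0.05),
    )
    def test_scale_homogeneity_of_fluctuations(self, p, r_e, r_i):
        """Doubling both rates multiplies each amplitude by sqrt(2)."""
        d1 = np.array(current_fluctuations(p, r_e, r_i))
        d2 = np.array(current_fluctuations(p, 2 * r_e, 2 * r_i))
        assert d2 == pytest.approx(d1 * np.sqrt(2.0), rel=1e-12)

    def test_monotone_in_each_rate(self, async_params):
        base = current_fluctuations(async_params, 3e-3, 1e-2)
        up_e = current_fluctuations(async_params, 4e-3, 1e-2)
        up_i = current_fluctuations(async_params, 3e-3, 2e-2)
        assert up_e[0] > base[0] and up_e[1] > base[1]
        assert up_i[0] > base[0] and up_i[1] > base[1]
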