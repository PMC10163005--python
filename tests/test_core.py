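"""Regulatory functions, allocation rules and derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sectorsize as ss
from sectorsize import core
from sectorsize.errors import (ConstraintViolation, DomainError,
                               ParameterError)

PARAMS = ss.preset("upshift")[0]


class TestRegulatoryFunctions:
    @pytest.mark.parametrize("a_rel, expected", [
        (0.0, 1.0), (1.0, 0.5), (3.0, 0.1)])
    def test_feedback_inhibition_values(self, a_rel, expected):
        a_n = 1e-3
        assert ss.f_inhibition(a_rel * a_n, a_n) == pytest.approx(expected)

    @pytest.mark.parametrize("a_rel, expected", [
        (0.0, 0.0), (1.0, 0.5), (3.0, 0.9)])
    def test_translation_attenuation_values(self, a_rel, expected):
        a_t = 1e-4
        assert ss.g_attenuation(a_rel * a_t, a_t) == pytest.approx(expected)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            ss.f_inhibition(1e-3, 0.0)
        with pytest.raises(ParameterError):
            ss.g_attenuation(1e-3, -1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(a=st.floats(min_value=0, max_value=1.0),
           b=st.floats(min_value=1e-8, max_value=1.0))
    def test_bounds_and_monotonicity(self, a, b):
        """f and g stay in [0, 1]; f decreases and g increases in a."""
        f1, f2 = ss.f_inhibition(a, 1e-3), ss.f_inhibition(a + b, 1e-3)
        g1, g2 = ss.g_attenuation(a, 1e-4), ss.g_attenuation(a + b, 1e-4)
        assert 0 < f1 <= 1 and 0 <= g1 < 1
        assert f2 < f1
        assert g2 > g1


class TestRibosomalAllocation:
    def test_starvation_limit_is_inactive_floor(self):
        assert ss.allocation_fR(0.0, PARAMS) == pytest.approx(
            PARAMS.phi_R_min, rel=1e-12)

    def test_saturation_limit_is_max_allocation(self):
        assert ss.allocation_fR(1e6, PARAMS) == pytest.approx(
            PARAMS.phi_R_max, rel=1e-9)

    def test_bounded_and_nondecreasing_on_log_grid(self):
        a = np.logspace(np.log10(PARAMS.a_t / 100),
                        np.log10(100 * PARAMS.a_n), 400)
        fr = ss.allocation_fR(a, PARAMS)
        assert np.all(fr >= PARAMS.phi_R_min - 1e-12)
        assert np.all(fr <= PARAMS.phi_R_max + 1e-12)
        assert np.all(np.diff(fr) >= -1e-12)

    def test_matches_flux_maximization_oracle(self):
        """f_R*(a) passes through the brute-force steady-state flux optimum.

        Oracle: parameterize the flux-balance manifold by a (for each a
        the balanced allocation is closed form), grid-search the
        translational flux maximum, and compare the optimizing
        allocation with allocation_fR at the optimizing a.
        """
        rng = np.random.default_rng(42)
        for _ in range(8):
            phi_min = rng.uniform(0.02, 0.15)
            phi_max = rng.uniform(phi_min + 0.2, 0.8)
            a_t = 10 ** rng.uniform(-5, -3.5)
            a_n = a_t * 10 ** rng.uniform(0.5, 1.5)
            p = ss.ModelParams(phi_R_min=phi_min, phi_R_max=phi_max,
                               a_t=a_t, a_n=a_n,
                               kappa_t0=rng.uniform(1, 6), mu_ns=0.0)
            kn0 = rng.uniform(2, 100)
            a = np.logspace(np.log10(a_t) - 2, np.log10(a_n) + 2, 4000)
            f = ss.f_inhibition(a, p.a_n)
            g = ss.g_attenuation(a, p.a_t)
            # flux balance at fixed allocation: kn0 f (phimax - fR) = kt g (fR - phimin)
            fr_balance = (kn0 * f * p.phi_R_max
                          + p.kappa_t0 * g * p.phi_R_min) / \
                (kn0 * f + p.kappa_t0 * g)
            J = p.kappa_t0 * g * (fr_balance - p.phi_R_min)
            i = int(np.argmax(J))
            assert 0 < i < a.size - 1, "optimum must be interior"
            assert ss.allocation_fR(a[i], p) == pytest.approx(
                fr_balance[i], abs=5e-3 * p.delta_phi)


class TestDivisionAllocation:
    def test_requires_separated_parameters(self):
        with pytest.raises(ParameterError):
            ss.allocation_fX(0.3, PARAMS)

    def test_linearity_and_basal_limit(self, separated_params):
        p = separated_params
        assert ss.allocation_fX(p.phi_R_max, p) == pytest.approx(p.beta)
        delta = 0.1
        assert ss.allocation_fX(p.phi_R_max - delta, p) == pytest.approx(
            p.alpha * delta + p.beta)

    def test_out_of_range_allocation_rejected(self, separated_params):
        with pytest.raises(DomainError):
            ss.allocation_fX(separated_params.phi_R_max + 0.01,
                             separated_params)

    def test_composite_scaling(self):
        fr = 0.3
        assert ss.gamma_fX(fr, PARAMS) == pytest.approx(
            PARAMS.gamma_alpha * (PARAMS.phi_R_max - fr) + PARAMS.gamma_beta)


class TestRatesAndDerivatives:
    def test_growth_rate_floor_is_degradation(self):
        p = PARAMS.evolve(mu_ns=0.1)
        assert ss.growth_rate(p.phi_R_min, 0.01, p) == pytest.approx(-0.1)
        assert ss.growth_rate(0.4, 0.0, p) == pytest.approx(-0.1)

    def test_kP_vanishes_without_translational_flux(self):
        p = PARAMS.evolve(mu_ns=0.1)
        assert ss.kP_instantaneous(0.3, -p.mu_ns, p) == pytest.approx(0.0)

    def test_kP_persists_in_stationary_phase(self):
        """k_P = gamma f_X mu_ns > 0 at kappa = 0 with protein turnover."""
        p = PARAMS.evolve(mu_ns=0.1)
        kP = ss.kP_instantaneous(0.1, 0.0, p)
        assert kP == pytest.approx(ss.gamma_fX(0.1, p) * 0.1)
        assert kP > 0

    def test_fixed_point_derivatives_vanish(self, upshift_setup, rich_steady):
        params, _, kn_high = upshift_setup
        state = ss.CellState(a=rich_steady.a_star,
                             phi_R=rich_steady.phi_R_star, phi_X=0.0,
                             V=1.0, X_tilde=0.0)
        d = ss.state_derivatives(state, kn_high, params)
        assert abs(d[0]) < 1e-8   # da/dt
        assert abs(d[1]) < 1e-10  # dphi_R/dt

    def test_inactive_ribosome_floor_shrinks_cell(self):
        p = PARAMS.evolve(mu_ns=0.1)
        state = ss.CellState(a=1e-3, phi_R=p.phi_R_min, phi_X=0.0, V=2.0,
                             X_tilde=0.0)
        d = ss.state_derivatives(state, 5.0, p)
        assert d[1] == pytest.approx(0.0)            # dphi_R/dt
        assert d[3] == pytest.approx(-p.mu_ns * 2.0)  # dV/dt = -mu_ns V

    def test_finite_difference_against_integration(self, upshift_setup,
                                                   poor_initial):
        """Derivatives agree with (s(t+h) - s(t)) / h along a trajectory."""
        params, kn_low, _ = upshift_setup
        env = ss.Environment.constant(kn_low)
        # start off the fixed point so derivatives are nonzero
        initial = poor_initial.replace(a=poor_initial.a * 2.0, X_tilde=0.1)
        h = 1e-7  # truncation error ~ h * (fast amino-acid timescale)^-1
        traj = ss.integrate(initial, env, params, 2 * h, division=False,
                            rtol=1e-12, atol=1e-14)
        d = ss.state_derivatives(initial, kn_low, params)
        fd = (traj.states[-1] - traj.states[0]) / traj.times[-1]
        np.testing.assert_allclose(fd, d, rtol=2e-4, atol=1e-10)

    def test_degenerate_degradation_matches_vector_form(self, separated_params):
        """With mu_X = mu_ns the X-sector equation reduces to the shared form."""
        p = separated_params.evolve(mu_ns=0.1, mu_X=0.1)
        state = ss.CellState(a=3e-4, phi_R=0.3, phi_X=0.01, V=1.0,
                             X_tilde=0.2)
        d = ss.state_derivatives(state, 10.0, p)
        f_R = ss.allocation_fR(state.a, p)
        f_X = ss.allocation_fX(f_R, p)
        J_t = ss.translational_flux(state.phi_R, state.a, p)
        assert d[2] == pytest.approx(J_t * (f_X - state.phi_X), rel=1e-14)

    def test_negative_metabolic_sector_signalled(self, separated_params):
        state = ss.CellState(a=3e-4, phi_R=0.56, phi_X=0.05, V=1.0,
                             X_tilde=0.0)
        with pytest.raises(ConstraintViolation):
            ss.state_derivatives(state, 10.0, separated_params)


class TestParamValidation:
    @pytest.mark.parametrize("changes", [
        dict(phi_R_min=0.6),                 # min above max
        dict(a_t=1e-2),                      # a_t above a_n
        dict(kappa_t0=-1.0),
        dict(gamma_beta=0.0),
        dict(alpha=0.1),                     # alpha without beta
        dict(alpha=0.1, beta=0.5),           # inconsistent composites
    ])
    def test_invariants_enforced(self, changes):
        with pytest.raises(ParameterError):
            PARAMS.evolve(**changes)

    def test_derived_constants(self):
        assert PARAMS.delta_phi == pytest.approx(0.501)
        assert PARAMS.kappa_max == pytest.approx(2.6 * 0.501)
        assert PARAMS.V0_max == pytest.approx(1 / 1.1)

    def test_cellstate_invariants(self):
        with pytest.raises(DomainError):
            ss.CellState(a=-1e-3, phi_R=0.3, phi_X=0.0, V=1.0, X_tilde=0.0)
        with pytest.raises(DomainError):
            ss.CellState(a=1e-3, phi_R=0.3, phi_X=0.0, V=0.0, X_tilde=0.0)
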