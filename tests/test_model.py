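"""Pointwise model functions: indicator, sensitivity, drift, reactions,
uniform steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from thymosim import (
    FieldState,
    Grid,
    ModelParams,
    InvalidParameterError,
    chemotactic_sensitivity,
    drift_velocity,
    homogeneous_steady_state,
    indicator_phi,
    reaction_terms,
    rhs,
)
from thymosim.model import _steady_residual
from thymosim.units import audit_units


class TestIndicator:
    @pytest.mark.parametrize("rho,mu,expected", [
        (0.0, 1e-4, 1.0),          # empty medulla -> pure cortex
        (1e-4, 1e-4, 0.5),         # half-point at the density scale
        (3e-4, 1e-4, 0.1),         # 1/(1+9)
    ])
    def test_values(self, rho, mu, expected):
        assert indicator_phi(rho, mu) == pytest.approx(expected, rel=1e-12)

    def test_invalid_mu(self):
        with pytest.raises(InvalidParameterError):
            indicator_phi(1e-4, 0.0)

    @given(st.floats(min_value=0, max_value=1e2, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, r):
        mu = 1e-4
        val = indicator_phi(r * mu, mu)
        assert 0.0 < val <= 1.0
        assert indicator_phi((r + 0.5) * mu, mu) < val  # strictly decreasing


class TestSensitivity:
    def test_values(self):
        assert chemotactic_sensitivity(0.0, 5.0) == pytest.approx(0.2)
        assert chemotactic_sensitivity(5.0, 5.0) == pytest.approx(0.05)

    @given(st.floats(min_value=0, max_value=1e3, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_algebraic_identity_and_bounds(self, c):
        K = 5.0
        chi = chemotactic_sensitivity(c, K)
        assert chi * (K + c) ** 2 / K == pytest.approx(1.0, rel=1e-12)
        assert 0.0 < chi <= 1.0 / K

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            chemotactic_sensitivity(-1.0, 5.0)


class TestDriftVelocity:
    def test_uniform_chemokine_gives_zero(self, wt, grid2d_small):
        c = np.full(grid2d_small.shape, 2.0)
        v = drift_velocity(c, wt, grid2d_small)
        for comp in v:
            assert np.abs(comp).max() < 1e-12

    def test_chemotaxis_off_gives_zero(self, wt, grid2d_small):
        x = grid2d_small.meshgrid()[0]
        c = 1.0 + np.sin(2 * np.pi * x / grid2d_small.L)
        v = drift_velocity(c, wt.with_overrides(chemotaxis_on=False), grid2d_small)
        assert all(np.abs(comp).max() == 0.0 for comp in v)

    def test_single_mode_matches_analytic_formula_nodewise(self, wt, grid2d_small):
        """v_C = T χ(ρC) ∂x ρC for a smooth periodic profile, at every node."""
        g = grid2d_small
        x = g.meshgrid()[0]
        amp, k = 1.5, 2 * np.pi / g.L
        c = 2.0 + amp * np.sin(k * x)
        v = drift_velocity(c, wt, g)
        expected = wt.T_chi * chemotactic_sensitivity(c, wt.K_offon) * amp * k * np.cos(k * x)
        np.testing.assert_allclose(v[0], expected, rtol=1e-9, atol=1e-9 * np.abs(expected).max())
        assert np.abs(v[1]).max() < 1e-9 * np.abs(expected).max()

    def test_shape_mismatch_raises(self, wt, grid2d_small):
        with pytest.raises(Exception):
            drift_velocity(np.zeros((8, 8)), wt, grid2d_small)


class TestReactionTerms:
    def test_empty_state_produces_only_thymocytes(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        f = reaction_terms(s, wt)
        np.testing.assert_allclose(f["rho_T"], wt.p)
        for name in ("rho_Tstar", "rho_M", "rho_C"):
            np.testing.assert_allclose(f[name], 0.0)

    def test_carrying_capacity_limit(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        s.rho_M[:] = wt.K_cap
        s.rho_Tstar[:] = 1e-5
        f = reaction_terms(s, wt)
        np.testing.assert_allclose(f["rho_M"], -wt.k_m * wt.K_cap, rtol=1e-12)

    def test_hand_evaluated_point(self, wt, grid2d_small):
        """Each term evaluated independently at ρT = ρM = 1e-4, ρT* = ρC = 0."""
        s = FieldState.zeros(grid2d_small)
        s.rho_T[:] = 1e-4
        s.rho_M[:] = 1e-4
        f = reaction_terms(s, wt)
        activation = wt.k_r * 1e-4 * 1e-4            # 1.5e-5
        production = wt.p * 0.5                      # φ(μ) = 1/2
        np.testing.assert_allclose(f["rho_T"], -activation + production, rtol=1e-12)
        np.testing.assert_allclose(f["rho_Tstar"], activation, rtol=1e-12)
        np.testing.assert_allclose(f["rho_C"], wt.k_e * 1e-4, rtol=1e-12)

    def test_frozen_medulla_has_zero_mtec_rate(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        s.rho_M[:] = 2e-4
        s.rho_Tstar[:] = 1e-5
        f = reaction_terms(s, wt.with_overrides(medulla_frozen=True))
        np.testing.assert_allclose(f["rho_M"], 0.0)

    def test_exit_and_tolerant_terms(self, grid2d_small):
        params = ModelParams(exit_term_on=True, tolerant_on=True)
        s = FieldState.zeros(grid2d_small, tolerant=True)
        s.rho_T[:] = 1e-5
        s.rho_T0[:] = 2e-5
        f = reaction_terms(s, params)
        np.testing.assert_allclose(f["rho_T"], params.p - params.k_ex * 1e-5, rtol=1e-12)
        np.testing.assert_allclose(f["rho_T0"], params.p - params.k_ex * 2e-5, rtol=1e-12)


class TestRHS:
    def test_uniform_state_reduces_to_reactions(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        s.rho_T[:] = 1e-5
        s.rho_Tstar[:] = 2e-6
        s.rho_M[:] = 2e-4
        s.rho_C[:] = 1.0
        full = rhs(s, wt, grid2d_small)
        local = reaction_terms(s, wt)
        for name in local:
            scale = max(np.abs(local[name]).max(), 1e-30)
            np.testing.assert_allclose(full[name], local[name], atol=1e-10 * scale)

    def test_transport_integrals_vanish(self, wt, grid2d_small, rng):
        """Periodic BCs annihilate domain integrals of diffusion + advection."""
        g = grid2d_small
        x, y = g.meshgrid()
        k = 2 * np.pi / g.L
        s = FieldState.zeros(g)
        s.rho_T = 1e-5 * (1.2 + np.sin(k * x) * np.cos(2 * k * y))
        s.rho_Tstar = 2e-6 * (1.1 + np.cos(k * y))
        s.rho_M = 2e-4 * (1.0 + 0.8 * np.sin(k * x + k * y)) / 1.8
        s.rho_C = 1.0 + 0.5 * np.cos(k * x)
        full = rhs(s, wt, g)
        local = reaction_terms(s, wt)
        for name in local:
            transport = g.integrate(full[name] - local[name])
            scale = g.integrate(np.abs(local[name]))
            assert abs(transport) < 1e-10 * scale

    def test_total_thymocyte_budget(self, wt, grid2d_small):
        """d/dt ∫(ρT + ρT*) = ∫(p φ(ρM) − d ρT*): activation cancels in the sum."""
        g = grid2d_small
        x, _ = g.meshgrid()
        k = 2 * np.pi / g.L
        s = FieldState.zeros(g)
        s.rho_T = 1e-5 * (1.0 + 0.5 * np.sin(k * x))
        s.rho_Tstar = 3e-6 * (1.0 + 0.4 * np.cos(k * x))
        s.rho_M = 1.5e-4 * (1.0 + 0.9 * np.sin(2 * k * x)) / 1.9
        s.rho_C = 0.8 + 0.3 * np.sin(k * x)
        full = rhs(s, wt, g)
        lhs = g.integrate(full["rho_T"] + full["rho_Tstar"])
        expected = g.integrate(wt.p * indicator_phi(s.rho_M, wt.mu) - wt.d * s.rho_Tstar)
        assert lhs == pytest.approx(expected, rel=1e-9)


class TestHomogeneousSteadyState:
    def test_residuals_below_tolerance(self, wt, grid2d_small):
        ss = homogeneous_steady_state(wt)
        assert ss.nontrivial, "wild-type parameters admit a nontrivial uniform state"
        for state in ss.nontrivial:
            f = reaction_terms(state.to_fields(grid2d_small), wt)
            # compare each residual against the scale of its largest term
            scales = {
                "rho_T": wt.p,
                "rho_Tstar": wt.d * state.rho_Tstar,
                "rho_M": wt.k_m * state.rho_M,
                "rho_C": wt.k_c * state.rho_C,
            }
            for name, scale in scales.items():
                assert abs(float(f[name][0, 0])) < 1e-8 * scale

    def test_chemokine_balance_exact(self, wt):
        for state in homogeneous_steady_state(wt).nontrivial:
            assert state.rho_C == pytest.approx(wt.k_e * state.rho_M / wt.k_c, rel=1e-12)

    def test_against_dense_scan_oracle(self, wt):
        """Brute-force residual scan over 1e6 points in (0, K) brackets the root."""
        ms = np.linspace(1e-9 * wt.K_cap, wt.K_cap * (1 - 1e-9), 1_000_000)
        res = _steady_residual(ms, wt)
        crossings = ms[np.nonzero(np.diff(np.sign(res)))[0]]
        roots = homogeneous_steady_state(wt).nontrivial
        assert len(roots) == len(crossings)
        for root, approx in zip(roots, sorted(crossings)):
            assert abs(root.rho_M - approx) < 1e-6 * wt.K_cap

    def test_trivial_branch_reporting(self, wt):
        no_exit = homogeneous_steady_state(wt)
        assert no_exit.trivial is None
        assert "no finite trivial state" in no_exit.trivial_note
        with_exit = homogeneous_steady_state(wt.with_overrides(exit_term_on=True))
        assert with_exit.trivial is not None
        assert with_exit.trivial.rho_T == pytest.approx(wt.p / wt.k_ex)
        assert with_exit.trivial.rho_M == 0.0

    def test_uniform_initial_ode_relaxes_to_root(self, wt):
        """An ODE integration of the reaction system converges to the computed root."""
        ss = homogeneous_steady_state(wt).patterned_branch

        def f(_, y):
            g = FieldState(0.0, *(np.array([[v]]) for v in y))
            rates = reaction_terms(g, wt)
            return [float(rates[n][0, 0]) for n in ("rho_T", "rho_Tstar", "rho_M", "rho_C")]

        y0 = ss.as_array() * 1.05  # nudge off the fixed point
        sol = solve_ivp(f, (0, 20000), y0, rtol=1e-10, atol=1e-16, method="LSODA")
        np.testing.assert_allclose(sol.y[:, -1], ss.as_array(), rtol=1e-5)


def test_units_audit_passes():
    terms = audit_units()
    assert "T/advection" in terms and "C/emission" in terms
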