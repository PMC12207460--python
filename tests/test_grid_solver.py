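"""Spectral grid operators and ETD1 time integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thymosim import (
    FieldState,
    Grid,
    ModelParams,
    homogeneous_steady_state,
    integrate,
    quasi_steady_check,
    reaction_terms,
    step,
)
from thymosim.grid import GridResolutionWarning
from thymosim.solver import Trajectory, _diag_row
from thymosim.stability import growth_rate, jacobian


class TestGrid:
    def test_spacing(self):
        g = Grid.make(2, 128, 3000.0)
        assert g.dx == pytest.approx(23.4375)

    def test_resolution_warning(self):
        with pytest.warns(GridResolutionWarning):
            g = Grid.make(3, 64, 3000.0)
        assert g.dx == pytest.approx(46.875)

    def test_laplacian_eigenfunction_spectrally_exact(self):
        g = Grid(2, 64, 1500.0)
        x = g.meshgrid()[0]
        k = 2 * np.pi / g.L
        f = np.sin(k * x)
        lap = g.laplacian(f)
        np.testing.assert_allclose(lap, -(k**2) * f, atol=1e-12 * k**2)

    def test_gradient_divergence_adjointness(self, rng):
        g = Grid(2, 32, 750.0)
        f = rng.random(g.shape)
        h = rng.random(g.shape)
        gf = g.gradient(f)
        # ∫ h ∇·(∇f) = −∫ ∇h·∇f for periodic fields
        lhs = g.integrate(h * g.divergence(gf))
        gh = g.gradient(h)
        rhs_val = -g.integrate(sum(a * b for a, b in zip(gh, gf)))
        assert lhs == pytest.approx(rhs_val, rel=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            Grid(4, 32, 100.0)
        with pytest.raises(ValueError):
            Grid(2, 8, 100.0)


class TestStep:
    def test_zero_dt_is_identity(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        s.rho_M[:] = 1e-4
        out = step(s, 0.0, wt, grid2d_small)
        for (_, a), (_, b) in zip(s.items(), out.items()):
            np.testing.assert_array_equal(a, b)

    def test_pure_diffusion_mode_decays_exactly(self):
        """With all rates zero the spectral propagator is the heat kernel."""
        params = ModelParams(
            T_chi=0.0, p=0.0, d=0.0, k_r=0.0, k_b=0.0, k_m=0.0,
            k_e=0.0, k_c=0.0, chemotaxis_on=False)
        g = Grid(2, 32, 750.0)
        x = g.meshgrid()[0]
        k = 2 * np.pi / g.L
        s = FieldState.zeros(g)
        s.rho_T = 1.0 + 0.5 * np.sin(k * x)
        dt = 0.05
        out = step(s, dt, params, g)
        decay = np.exp(-params.D_T * k**2 * dt)
        expected = 1.0 + 0.5 * decay * np.sin(k * x)
        np.testing.assert_allclose(out.rho_T, expected, rtol=1e-12, atol=1e-13)

    def test_uniform_state_matches_ode_oracle(self, wt, grid2d_small):
        """One step on a uniform state agrees with a high-accuracy ODE solve
        of the homogeneous reaction system to O(dt²)."""
        names = ("rho_T", "rho_Tstar", "rho_M", "rho_C")
        y0 = np.array([1e-5, 1e-6, 2e-4, 1.0])

        def f(_, y):
            s = FieldState(0.0, *(np.array([[v]]) for v in y))
            rates = reaction_terms(s, wt)
            return [float(rates[n][0, 0]) for n in names]

        errs = []
        for dt in (0.2, 0.1):
            s = FieldState.zeros(grid2d_small)
            for name, v in zip(names, y0):
                getattr(s, name)[:] = v
            out = step(s, dt, wt, grid2d_small)
            sol = solve_ivp(f, (0, dt), y0, rtol=1e-12, atol=1e-20)
            got = np.array([float(getattr(out, n)[0, 0]) for n in names])
            errs.append(np.abs((got - sol.y[:, -1]) / sol.y[:, -1]).max())
        # halving dt must reduce the one-step error ~4x (local order 2)
        assert errs[1] < errs[0] / 2.5
        assert errs[0] < 5e-2


class TestIntegrate:
    def test_zero_horizon_returns_initial_state(self, wt, grid2d_small):
        s = FieldState.zeros(grid2d_small)
        traj = integrate(s, 0.0, wt, grid2d_small)
        assert len(traj.snapshots) == 1
        assert traj.final.t == 0.0

    def test_frozen_medulla_chemokine_relaxation(self, grid2d_small):
        """ρC → k_e ρM / k_c: linear relaxation leaves a residual e^{-k_c t},
        below 1e-6 once k_c t = 20."""
        params = ModelParams(medulla_frozen=True, chemotaxis_on=False)
        s = FieldState.zeros(grid2d_small)
        s.rho_M[:] = 2e-4
        traj = integrate(s, 20.0 / params.k_c, params, grid2d_small, dt_max=0.01)
        target = params.k_e * 2e-4 / params.k_c
        np.testing.assert_allclose(traj.final.rho_C, target, rtol=1e-6)
        # frozen medulla is bitwise constant
        np.testing.assert_array_equal(traj.final.rho_M, s.rho_M)

    def test_homogeneous_steady_state_is_invariant(self, wt, grid2d_small):
        ss = homogeneous_steady_state(wt).patterned_branch
        s0 = ss.to_fields(grid2d_small)
        traj = integrate(s0, 100.0, wt, grid2d_small, dt_max=0.1)
        for name, arr in traj.final.items():
            ref = float(getattr(ss, name))
            assert np.abs(arr - ref).max() < 1e-8 * ref

    def test_positivity_and_clipping_bookkeeping(self, wt):
        """Seeded run keeps all recorded fields non-negative; the logged
        negative-undershoot mass per step stays a small fraction of the
        mTEC mass once the fronts have developed."""
        from thymosim import SeedSpec, seeded_initial_state
        g = Grid(2, 32, 750.0)
        s0 = seeded_initial_state(g, SeedSpec(n_seeds=4, amplitude=wt.K_cap, rng_seed=7))
        traj = integrate(s0, 300.0, wt, g, diag_every=20)
        df = traj.diagnostics_frame()
        for name in ("rho_T", "rho_Tstar", "rho_M", "rho_C"):
            assert df[f"min_{name}"].min() >= 0.0
        # per-step clipped mass over the last diagnostics interval
        tail = df.iloc[-2:]
        n_steps = 20
        per_step = (tail["clipped_mass"].iloc[-1] - tail["clipped_mass"].iloc[0]) / n_steps
        total_M = df["mean_rho_M"].iloc[-1] * g.volume
        assert per_step < 1e-5 * total_M

    def test_first_order_global_convergence(self):
        """Halving dt halves the error against a fine-dt reference (ETD1)."""
        from thymosim import SeedSpec, seeded_initial_state
        params = ModelParams(chemotaxis_on=False)
        g = Grid(2, 32, 750.0)
        s0 = seeded_initial_state(g, SeedSpec(n_seeds=4, amplitude=params.K_cap, rng_seed=3))
        finals = {}
        for dt in (0.2, 0.1, 0.0125):
            finals[dt] = integrate(s0, 50.0, params, g, dt_max=dt).final
        ref = finals[0.0125].rho_M
        e1 = np.abs(finals[0.2].rho_M - ref).max()
        e2 = np.abs(finals[0.1].rho_M - ref).max()
        assert 1.5 < e1 / e2 < 3.5

    def test_linear_growth_rate_matches_dispersion(self, wt):
        """A single unstable Fourier mode seeded on the uniform state grows
        at the rate predicted by the linear stability analysis (within 2%)."""
        params = wt.with_overrides(T_chi=1e6)  # strongly unstable -> short fit window
        ss = homogeneous_steady_state(params).patterned_branch
        # place the fastest-growing mode exactly on the grid
        from thymosim import dispersion_relation
        disp = dispersion_relation(params)
        m = 2
        L = 2 * np.pi * m / disp.q_star
        g = Grid(2, 64, L)
        q = 2 * np.pi * m / g.L
        lam_pred = growth_rate(q, ss, params)

        J = jacobian(q, ss, params)
        w, V = np.linalg.eig(J)
        v = np.real(V[:, np.argmax(w.real)])
        x = g.meshgrid()[0]
        mode = np.cos(q * x)
        s0 = ss.to_fields(g)
        eps = 1e-6
        scales = ss.as_array()
        for i, name in enumerate(("rho_T", "rho_Tstar", "rho_M", "rho_C")):
            getattr(s0, name)[:] += eps * scales.max() * v[i] * mode

        t_fit = 2.0 / abs(lam_pred)
        traj = integrate(s0, t_fit, params, g, dt_max=0.05,
                         output_schedule=np.linspace(t_fit / 4, t_fit, 4))
        amps, times = [], []
        for s in traj.snapshots[1:]:
            coeff = np.abs(g.fft(s.rho_M - s.rho_M.mean())[m, 0])
            amps.append(coeff)
            times.append(s.t)
        lam_measured = np.polyfit(times, np.log(amps), 1)[0]
        assert lam_measured == pytest.approx(lam_pred, rel=0.02)


class TestQuasiSteady:
    def _traj(self, rows, wt, grid2d_small):
        return Trajectory(wt, grid2d_small, [], rows)

    def test_constant_trajectory_is_quasi_steady(self, wt, grid2d_small):
        rows = [{"t": float(t), "mean_rho_M": 2e-4, "phi_M": 0.4} for t in range(0, 501, 50)]
        ok, drifts = quasi_steady_check(self._traj(rows, wt, grid2d_small), window=200.0)
        assert ok
        assert all(v == 0.0 for v in drifts.values())

    def test_growing_trajectory_is_not_quasi_steady(self, wt, grid2d_small):
        rows = [{"t": float(t), "mean_rho_M": 2e-4 * np.exp(0.1 * t), "phi_M": 0.4}
                for t in range(0, 501, 50)]
        ok, drifts = quasi_steady_check(self._traj(rows, wt, grid2d_small), window=200.0)
        assert not ok
        assert drifts["mean_rho_M"] > 1.0  # far above 1% per 100 h
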