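"""Time integration of the cross-talk model on periodic grids.

Scheme
------
First-order exponential-integrator IMEX (ETD1).  For each field u with
diffusivity D and constant linear decay γ (the deletion, exit, decay and
degradation rates), the update in Fourier space is

    û(t+dt) = e^{L dt} û(t) + dt φ1(L dt) N̂(t),   L = −D|q|² − γ,

with φ1(z) = (e^z − 1)/z.  Diffusion and the constant-coefficient decays
are therefore integrated exactly; the remaining reactions and the
chemotactic flux divergence ∇·(ρ v_C) are explicit.  The quadratic flux
is evaluated pseudospectrally with 2/3-rule dealiasing.

The step size is capped by the advective CFL condition (safety 0.5), an
explicit-reaction rate bound and a user dt_max; negative undershoots are
clipped to zero and the clipped mass is logged per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import FieldState
from .grid import Grid
from .model import (
    ADVECTED,
    DIFFUSIVITY_OF,
    NumericalFailureError,
    chemotactic_sensitivity,
    indicator_phi,
)
from .params import ModelParams


def _linear_decay_rates(params: ModelParams) -> dict[str, float]:
    """Constant linear decay γ folded into the exponential propagator."""
    g = {
        "rho_T": params.k_ex if params.exit_term_on else 0.0,
        "rho_Tstar": params.d,
        "rho_M": params.k_m,
        "rho_C": params.k_c,
    }
    if params.tolerant_on:
        g["rho_T0"] = params.k_ex
    return g


class _Propagators:
    """Cached e^{L dt} and dt·φ1(L dt) arrays per field for one dt."""

    def __init__(self, params: ModelParams, grid: Grid, dt: float):
        self.dt = dt
        gammas = _linear_decay_rates(params)
        self.E: dict[str, np.ndarray] = {}
        self.P1: dict[str, np.ndarray] = {}
        for name, gamma in gammas.items():
            D = getattr(params, DIFFUSIVITY_OF[name])
            L = -(D * grid.k2 + gamma)
            z = L * dt
            E = np.exp(z)
            # dt·φ1(z) with the z→0 limit dt
            with np.errstate(divide="ignore", invalid="ignore"):
                P1 = np.where(np.abs(z) > 1e-12, (E - 1.0) / np.where(z == 0, 1.0, L), dt)
            self.E[name] = E
            self.P1[name] = P1


@dataclass
class StepDiagnostics:
    clipped_mass: dict[str, float] = dc_field(default_factory=dict)
    max_speed: float = 0.0


def _explicit_terms(u: dict[str, np.ndarray], chat: np.ndarray,
                    params: ModelParams, grid: Grid
                    ) -> tuple[dict[str, np.ndarray], float]:
    """Spectral explicit tendencies N̂ per evolving field and max drift speed."""
    P = params
    phi = indicator_phi(u["rho_M"], P.mu)
    act = P.k_r * u["rho_T"] * u["rho_M"]

    local: dict[str, np.ndarray] = {
        "rho_T": -act + P.p * phi,
        "rho_Tstar": act,
        "rho_C": P.k_e * u["rho_M"],
    }
    if not P.medulla_frozen:
        local["rho_M"] = P.k_b * u["rho_Tstar"] * u["rho_M"] * (1.0 - u["rho_M"] / P.K_cap)
    if P.tolerant_on and "rho_T0" in u:
        local["rho_T0"] = P.p_tolerant * phi

    Nhat = {name: grid.fft(arr) for name, arr in local.items()}

    max_speed = 0.0
    if P.taxis != 0.0:
        gradC = [grid.ifft(1j * ki * chat) for ki in grid.k]
        pref = P.taxis * chemotactic_sensitivity(np.maximum(u["rho_C"], 0.0), P.K_offon)
        v = [pref * g for g in gradC]
        max_speed = float(max(np.abs(vi).max() for vi in v))
        for name in ADVECTED:
            if name not in Nhat or name not in u:
                continue
            div_hat = np.zeros(grid.shape_r, dtype=complex)
            for ki, vi in zip(grid.k, v):
                div_hat += 1j * ki * grid.fft(u[name] * vi)
            Nhat[name] = Nhat[name] - grid.dealias * div_hat
    return Nhat, max_speed


class _SpectralIntegrator:
    """Marches the state in spectral space, keeping clipped real copies.

    The dynamical state is the set of Fourier coefficients; real-space
    copies (used for the nonlinear terms and for output) are clipped to
    non-negative values, with the clipped mass logged.
    """

    def __init__(self, state0: FieldState, params: ModelParams, grid: Grid):
        self.params, self.grid = params, grid
        self.t = state0.t
        self.u: dict[str, np.ndarray] = {name: arr.copy() for name, arr in state0.items()}
        self.uhat = {name: grid.fft(arr) for name, arr in self.u.items()}
        self.clipped: dict[str, float] = {}
        self.last_vmax: float | None = None
        self._props: _Propagators | None = None

    def advance(self, dt: float) -> None:
        grid, params = self.grid, self.params
        if self._props is None or self._props.dt != dt:
            self._props = _Propagators(params, grid, dt)
        props = self._props
        Nhat, vmax = _explicit_terms(self.u, self.uhat["rho_C"], params, grid)
        self.last_vmax = vmax
        for name, nh in Nhat.items():
            uh = props.E[name] * self.uhat[name] + props.P1[name] * nh
            unew = grid.ifft(uh)
            if not np.isfinite(unew).all():
                raise NumericalFailureError(
                    f"non-finite values in {name} after step (dt={dt})", field=name)
            neg = unew < 0.0
            if neg.any():
                self.clipped[name] = self.clipped.get(name, 0.0) + float(
                    -unew[neg].sum() * grid.cell_volume)
                unew[neg] = 0.0
            self.uhat[name] = uh
            self.u[name] = unew
        self.t += dt

    def state(self) -> FieldState:
        kw = {name: arr.copy() for name, arr in self.u.items()}
        return FieldState(t=self.t, **kw)

    def propose_dt(self, dt_max: float, cfl_safety: float) -> float:
        vmax = self.last_vmax
        if vmax is None:
            vmax = _max_drift_speed(self.u["rho_C"], self.params, self.grid)
        return _dt_from_limits(self.state_view(), self.params, self.grid,
                               dt_max, cfl_safety, vmax)

    def state_view(self) -> FieldState:
        return FieldState(t=self.t, **self.u)


def _dt_from_limits(state: FieldState, params: ModelParams, grid: Grid,
                    dt_max: float, cfl_safety: float, vmax: float) -> float:
    """CFL/reaction-limited step size (integer-divisor fraction of dt_max)."""
    limit = dt_max
    if vmax > 0:
        limit = min(limit, cfl_safety * grid.dx / vmax)
    rate = params.k_r * float(state.rho_M.max())
    if not params.medulla_frozen:
        rate = max(rate, params.k_b * float(state.rho_Tstar.max()))
    if rate > 0:
        limit = min(limit, 0.25 / rate)
    if limit >= dt_max:
        return dt_max
    return dt_max / np.ceil(dt_max / limit)


def _max_drift_speed(rho_C: np.ndarray, params: ModelParams, grid: Grid) -> float:
    if params.taxis == 0.0:
        return 0.0
    gradC = grid.gradient(rho_C)
    pref = params.taxis * chemotactic_sensitivity(
        np.maximum(rho_C, 0.0), params.K_offon)
    return max(float(np.abs(pref * g).max()) for g in gradC)


def propose_dt(state: FieldState, params: ModelParams, grid: Grid,
               dt_max: float, cfl_safety: float = 0.5) -> float:
    """Step-size proposal capped by the advective CFL bound and the
    explicit reaction rates."""
    vmax = _max_drift_speed(state.rho_C, params, grid)
    return _dt_from_limits(state, params, grid, dt_max, cfl_safety, vmax)


def step(state: FieldState, dt: float, params: ModelParams, grid: Grid,
         diag: StepDiagnostics | None = None) -> FieldState:
    """Advance the state by one ETD1 step of size dt."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0.0:
        return state.copy()
    integ = _SpectralIntegrator(state, params, grid)
    integ.advance(dt)
    if diag is not None:
        diag.clipped_mass.update(integ.clipped)
        diag.max_speed = integ.last_vmax or 0.0
    return integ.state()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Snapshots plus per-interval scalar diagnostics of one simulation."""

    params: ModelParams
    grid: Grid
    snapshots: list[FieldState]
    diagnostics: list[dict]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diagnostics)


def _diag_row(state: FieldState, params: ModelParams, grid: Grid,
              clipped: dict[str, float]) -> dict:
    row: dict[str, float] = {"t": state.t}
    for name, arr in state.items():
        row[f"min_{name}"] = float(arr.min())
        row[f"max_{name}"] = float(arr.max())
        row[f"mean_{name}"] = float(arr.mean())
    row["phi_M"] = float((state.rho_M > params.mu).mean())
    row["clipped_mass"] = float(sum(clipped.values()))
    return row


def integrate(state0: FieldState, t_max: float, params: ModelParams, grid: Grid,
              output_schedule: np.ndarray | list[float] | None = None,
              dt_max: float = 0.1, cfl_safety: float = 0.5,
              diag_every: int = 50, keep_snapshots: bool = True) -> Trajectory:
    """Integrate for a duration t_max with adaptive (CFL-capped) ETD1 stepping.

    ``t_max`` and the output schedule are measured from the initial
    state's time (continuation runs keep absolute timestamps).  Snapshots
    are recorded at the requested schedule plus the initial and final
    states; scalar diagnostics every ``diag_every`` steps.  The run is
    deterministic given the initial state and configuration.
    """
    state0.validate(grid)
    if params.tolerant_on and state0.rho_T0 is None:
        raise ValueError("tolerant_on requires a state with rho_T0")
    raw = [] if output_schedule is None else list(np.asarray(output_schedule).ravel())
    schedule = sorted(state0.t + float(s) for s in raw if 0.0 < s <= t_max)
    t_end = state0.t + t_max

    integ = _SpectralIntegrator(state0, params, grid)
    snapshots = [state0.copy()]
    diagnostics = [_diag_row(integ.state_view(), params, grid, integ.clipped)]

    next_out = schedule.pop(0) if schedule else np.inf
    n_steps = 0
    while integ.t < t_end - 1e-12:
        dt = integ.propose_dt(dt_max, cfl_safety)
        dt = min(dt, t_end - integ.t, next_out - integ.t)
        try:
            integ.advance(dt)
        except NumericalFailureError as err:
            raise NumericalFailureError(
                f"{err} at t={integ.t:.4g} (step {n_steps})", field=err.field
            ) from err
        n_steps += 1
        if integ.t >= next_out - 1e-9:
            if keep_snapshots:
                snapshots.append(integ.state())
            next_out = schedule.pop(0) if schedule else np.inf
        if n_steps % diag_every == 0:
            diagnostics.append(_diag_row(integ.state_view(), params, grid, integ.clipped))

    if abs(integ.t - snapshots[-1].t) > 1e-9:
        snapshots.append(integ.state())
    if abs(diagnostics[-1]["t"] - integ.t) > 1e-9:
        diagnostics.append(_diag_row(integ.state_view(), params, grid, integ.clipped))
    return Trajectory(params, grid, snapshots, diagnostics)


def quasi_steady_check(trajectory: Trajectory, window: float = 200.0,
                       tol_per_100h: float = 0.01) -> tuple[bool, dict[str, float]]:
    """Relative drift of ⟨ρM⟩ and φM over the trailing window.

    The state is quasi-steady iff both drift rates are below
    ``tol_per_100h`` (fractional change per 100 h).
    """
    df = trajectory.diagnostics_frame()
    t_end = df["t"].iloc[-1]
    tail = df[df["t"] >= t_end - window]
    if len(tail) < 2:
        raise ValueError("trajectory shorter than the requested window")
    drifts: dict[str, float] = {}
    for col in ("mean_rho_M", "phi_M"):
        a, b = tail[col].iloc[0], tail[col].iloc[-1]
        span = tail["t"].iloc[-1] - tail["t"].iloc[0]
        scale = abs(a) if abs(a) > 0 else 1.0
        drifts[col] = abs(b - a) / scale / max(span, 1e-12) * 100.0
    ok = all(v < tol_per_100h for v in drifts.values())
    return ok, drifts
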