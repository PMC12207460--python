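"""Initial-condition constructors and named in-silico experiments.

The default initial condition mirrors medullary ontogeny: the medulla
grows out of small scattered mTEC seeds (300 bumps of width 60 μm in the
reference 3 mm box), with all thymocyte and chemokine fields zero.  Seed
positions are drawn in continuum coordinates so that the same rng seed
yields the same initial mass on any grid resolution.

The experiment registry collects the named parameter configurations
studied with the model: the wild type and its production/degradation
variants, chemotaxis knockouts, thymocyte-localization runs, (p, d)
scans, and the fixed-morphology (frozen-medulla) recognition-rate
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .fields import FieldState
from .grid import Grid
from .morphometrics import (
    compute_metrics,
    effective_recognition_rate,
    medulla_mask,
    predicted_volume_fraction,
)
from .params import ModelParams
from .solver import Trajectory, integrate


class InfeasibleGeometryError(ValueError):
    """A fixed morphology cannot realize the requested mTEC total."""


# ---------------------------------------------------------------------------
# seeded initial conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSpec:
    """Randomly scattered medullary seed regions.

    Each seed is a radially symmetric solid ball of diameter ``width`` at
    density ``amplitude`` with a smooth (tanh, width/8) edge — a small
    region of mature medullary tissue.  ``n_seeds`` positions are drawn
    uniformly from the continuum periodic domain.  The ball profile (rather
    than a tapered bump of the same width) is required for the seeds to
    carry enough mTEC mass to nucleate medulla growth in three dimensions.
    """

    n_seeds: int = 300
    width: float = 60.0          # μm
    amplitude: float = 7.5e-4    # μm⁻³ (carrying capacity by default)
    rng_seed: int = 0


def default_seed_count(grid: Grid, reference_count: int = 300,
                       reference_L: float = 3000.0) -> int:
    """Seed count scaled to the domain at the reference seed density."""
    return max(1, round(reference_count * (grid.L / reference_L) ** grid.ndim))


def seed_positions(spec: SeedSpec, ndim: int, L: float) -> np.ndarray:
    """Continuum seed coordinates, shape (n_seeds, ndim), reproducible."""
    rng = np.random.default_rng(spec.rng_seed)
    return rng.uniform(0.0, L, size=(spec.n_seeds, ndim))


def bump_profile(r: np.ndarray, width: float, amplitude: float) -> np.ndarray:
    """Smooth solid ball: A·½(1 − tanh((r − w/2)/(w/8))).

    Self-similar in the width, so the deposited mass scales exactly as
    amplitude · width^ndim.
    """
    return amplitude * 0.5 * (1.0 - np.tanh((r - width / 2.0) / (width / 8.0)))


def seed_mass(width: float, amplitude: float, ndim: int) -> float:
    """Continuum mass of one seed (radial quadrature of the ball profile)."""
    r = np.linspace(0.0, 3.0 * width, 4096)
    prof = bump_profile(r, width, amplitude)
    shell = 2.0 * np.pi * r if ndim == 2 else 4.0 * np.pi * r**2
    return float(np.trapezoid(prof * shell, r))


def seeded_initial_state(grid: Grid, spec: SeedSpec,
                         tolerant: bool = False) -> FieldState:
    """ρM = sum of seed balls (periodic minimum-image), all else zero.

    Seeds narrower than the grid can resolve are deposited at an effective
    width of 3·dx with the amplitude rescaled to conserve each seed's
    continuum mass, and the rasterized field is rescaled so the deposited
    total equals the analytic total exactly — the initial mTEC mass is
    therefore independent of grid resolution.
    """
    if spec.width <= 0:
        raise ValueError("seed width must be positive")
    state = FieldState.zeros(grid, tolerant=tolerant)
    if spec.n_seeds == 0:
        return state
    w_eff = max(spec.width, 3.0 * grid.dx)
    amp_eff = spec.amplitude * (spec.width / w_eff) ** grid.ndim
    mesh = grid.meshgrid()
    rho = np.zeros(grid.shape)
    for pos in seed_positions(spec, grid.ndim, grid.L):
        r2 = np.zeros(grid.shape)
        for x, c in zip(mesh, pos):
            dxi = np.abs(x - c)
            dxi = np.minimum(dxi, grid.L - dxi)  # periodic minimum image
            r2 += dxi * dxi
        rho += bump_profile(np.sqrt(r2), w_eff, amp_eff)
    target = spec.n_seeds * seed_mass(w_eff, amp_eff, grid.ndim)
    total = float(rho.sum()) * grid.cell_volume
    if total > 0:
        rho *= target / total
    state.rho_M = rho
    return state


def noisy_uniform_state(grid: Grid, params: ModelParams,
                        rel_amplitude: float = 0.01,
                        rng_seed: int = 0) -> FieldState:
    """The nontrivial uniform steady state plus small multiplicative noise.

    An alternative initial condition probing the pattern-forming
    instability directly; requires a nontrivial uniform branch.
    """
    from .model import homogeneous_steady_state

    branch = homogeneous_steady_state(params).patterned_branch
    if branch is None:
        raise ValueError(
            "no nontrivial uniform steady state exists for these parameters; "
            "use a seeded initial condition instead")
    state = branch.to_fields(grid, tolerant=params.tolerant_on)
    rng = np.random.default_rng(rng_seed)
    for _, arr in state.items():
        arr *= 1.0 + rel_amplitude * rng.standard_normal(grid.shape)
        np.maximum(arr, 0.0, out=arr)
    return state


# ---------------------------------------------------------------------------
# fixed morphologies (frozen-medulla comparisons)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedMorphology:
    """A static medulla shape with a prescribed total mTEC content.

    ``interior_density`` sets the mTEC level inside the shape; the
    geometry (radius or stripe fill) is solved so the domain integral of
    ρM matches ``target_total_mTEC``, and the rasterized field is rescaled
    so the match is exact on the grid.
    """

    kind: str                      # "sphere" | "lamellae" | "uniform"
    target_total_mTEC: float       # ∫ρM over the domain, μm⁻³·μm^ndim
    interior_density: float = 3.75e-4
    period: float | None = None    # lamellae stripe period, μm
    edge_width: float | None = None  # smoothing width; default 1.5·dx


def fixed_morphology_state(grid: Grid, morph: FixedMorphology) -> FieldState:
    """Rasterize a frozen medulla; thymocyte and chemokine fields zero."""
    if morph.target_total_mTEC <= 0:
        raise InfeasibleGeometryError("target_total_mTEC must be positive")
    V = grid.volume
    rho0 = morph.interior_density
    state = FieldState.zeros(grid)

    if morph.kind == "uniform":
        state.rho_M = np.full(grid.shape, morph.target_total_mTEC / V)
        return state

    w = 1.5 * grid.dx if morph.edge_width is None else morph.edge_width
    mesh = grid.meshgrid()

    if morph.kind == "sphere":
        measure = morph.target_total_mTEC / rho0     # required area/volume
        if grid.ndim == 2:
            r = np.sqrt(measure / np.pi)
        else:
            r = (3.0 * measure / (4.0 * np.pi)) ** (1.0 / 3.0)
        if 2.0 * r > grid.L:
            raise InfeasibleGeometryError(
                f"sphere radius {r:.1f} μm does not fit in L = {grid.L} μm")
        center = grid.L / 2.0
        r2 = np.zeros(grid.shape)
        for x in mesh:
            dxi = np.abs(x - center)
            dxi = np.minimum(dxi, grid.L - dxi)
            r2 += dxi * dxi
        dist = np.sqrt(r2) - r
        profile = rho0 * 0.5 * (1.0 - np.tanh(dist / max(w, 1e-9)))
    elif morph.kind == "lamellae":
        if morph.period is None or morph.period <= 0:
            raise InfeasibleGeometryError("lamellae require a positive period")
        fill = morph.target_total_mTEC / (V * rho0)
        if not 0.0 < fill < 1.0:
            raise InfeasibleGeometryError(
                f"required fill fraction {fill:.3f} outside (0, 1); "
                "adjust interior_density or target")
        x = mesh[0]
        # signed distance to the nearest stripe (stripes centred per period)
        phase = np.mod(x, morph.period)
        half = fill * morph.period / 2.0
        dist = np.abs(phase - morph.period / 2.0) - half
        profile = rho0 * 0.5 * (1.0 - np.tanh(dist / max(w, 1e-9)))
    else:
        raise InfeasibleGeometryError(f"unknown morphology kind {morph.kind!r}")

    total = grid.integrate(profile)
    if total <= 0:
        raise InfeasibleGeometryError("rasterized morphology carries no mass")
    state.rho_M = profile * (morph.target_total_mTEC / total)
    return state


# ---------------------------------------------------------------------------
# experiment registry
# ---------------------------------------------------------------------------

#: parameter overrides of each named seeded experiment
SEEDED_EXPERIMENTS: dict[str, dict[str, Any]] = {
    "wt": {},
    "wt_hi_turnover": {"p": 2.5e-5, "d": 10.0},
    "insular": {"p": 1e-6},
    "swiss_cheese": {"p": 7e-6},
    "no_chemotaxis": {"chemotaxis_on": False},
    "localization": {"exit_term_on": True, "tolerant_on": True},
    "localization_no_chemotaxis": {
        "exit_term_on": True, "tolerant_on": True, "chemotaxis_on": False},
}

#: every experiment name accepted by :func:`run_experiment`
EXPERIMENT_NAMES = tuple(SEEDED_EXPERIMENTS) + (
    "pd_scan", "sphere_krec", "lamellae_krec", "sphere_then_dynamics",
    "localization_staged", "localization_staged_no_chemotaxis")


@dataclass
class ExperimentResult:
    name: str
    params: ModelParams
    grid: Grid
    rng_seed: int
    trajectory: Trajectory | None
    metrics: pd.DataFrame
    table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def final_metrics(self) -> pd.Series:
        return self.metrics.iloc[-1]


def _snapshot_schedule(t_max: float, n: int = 8) -> np.ndarray:
    return np.linspace(t_max / n, t_max, n)


def _metrics_frame(traj: Trajectory, params: ModelParams, grid: Grid) -> pd.DataFrame:
    rows = [compute_metrics(s, params, grid).__dict__ for s in traj.snapshots]
    return pd.DataFrame(rows)


def _run(state0: FieldState, params: ModelParams, grid: Grid, t_max: float,
         dt_max: float, n_snapshots: int = 8) -> tuple[Trajectory, pd.DataFrame]:
    traj = integrate(state0, t_max, params, grid,
                     output_schedule=_snapshot_schedule(t_max, n_snapshots),
                     dt_max=dt_max)
    return traj, _metrics_frame(traj, params, grid)


def mean_intramedullary_density(state: FieldState, mu: float) -> float:
    """Mean ρM over the thresholded medulla of a (quasi-steady) state."""
    mask = medulla_mask(state.rho_M, mu)
    if not mask.any():
        return float("nan")
    return float(state.rho_M[mask].mean())


def run_experiment(name: str, grid: Grid, rng_seed: int = 0,
                   overrides: dict[str, Any] | None = None,
                   base_params: ModelParams | None = None,
                   t_max: float = 2000.0, dt_max: float = 0.1,
                   n_snapshots: int = 8, **extra: Any) -> ExperimentResult:
    """Run one named experiment; fully reproducible from (name, overrides, seed).

    ``extra`` carries experiment-specific settings: ``target_total_mTEC``
    and ``interior_density`` for the fixed-morphology experiments,
    ``periods`` for ``lamellae_krec``, ``t_switch``/``t_end`` for
    ``sphere_then_dynamics``, ``p_factors``/``d_factors`` for ``pd_scan``.
    """
    if name not in EXPERIMENT_NAMES:
        raise ValueError(
            f"unknown experiment {name!r}; valid names: {sorted(EXPERIMENT_NAMES)}")
    base = base_params if base_params is not None else ModelParams()
    overrides = dict(overrides or {})

    if name in SEEDED_EXPERIMENTS:
        params = base.with_overrides(**{**SEEDED_EXPERIMENTS[name], **overrides})
        if extra.get("initial", "seeds") == "uniform":
            state0 = noisy_uniform_state(grid, params, rng_seed=rng_seed)
        else:
            spec = SeedSpec(n_seeds=extra.get("n_seeds", default_seed_count(grid)),
                            width=extra.get("seed_width", 60.0),
                            amplitude=params.K_cap, rng_seed=rng_seed)
            state0 = seeded_initial_state(grid, spec, tolerant=params.tolerant_on)
        traj, metrics = _run(state0, params, grid, t_max, dt_max, n_snapshots)
        result = ExperimentResult(name, params, grid, rng_seed, traj, metrics)
    elif name == "pd_scan":
        params = base.with_overrides(**overrides)
        table = pd_scan(grid, rng_seed=rng_seed, base_params=params,
                        t_max=t_max, dt_max=dt_max,
                        p_factors=extra.get("p_factors"),
                        d_factors=extra.get("d_factors"),
                        n_seeds=extra.get("n_seeds"))
        result = ExperimentResult(name, params, grid, rng_seed, None,
                                  pd.DataFrame(), table=table)
    elif name in ("sphere_krec", "sphere_then_dynamics"):
        result = _run_sphere(name, grid, rng_seed, base, overrides,
                             t_max, dt_max, n_snapshots, extra)
    elif name == "lamellae_krec":
        result = _run_lamellae(grid, rng_seed, base, overrides, t_max, dt_max, extra)
    elif name.startswith("localization_staged"):
        result = _run_localization_staged(name, grid, rng_seed, base, overrides,
                                          t_max, dt_max, n_snapshots, extra)
    result.manifest = {
        "experiment": name, "rng_seed": rng_seed,
        "grid": {"ndim": grid.ndim, "n": grid.n, "L": grid.L},
        "t_max": t_max, "dt_max": dt_max,
        "params": result.params.to_dict(),
        "overrides": overrides,
    }
    return result


def _sphere_reference(grid: Grid, rng_seed: int, base: ModelParams,
                      t_max: float, dt_max: float,
                      extra: dict[str, Any]) -> tuple[float, float]:
    """(target total mTEC, interior density) from overrides or a wt companion run."""
    target = extra.get("target_total_mTEC")
    rho0 = extra.get("interior_density")
    if target is None or rho0 is None:
        wt = run_experiment("wt", grid, rng_seed=rng_seed, base_params=base,
                            t_max=t_max, dt_max=dt_max, n_snapshots=2)
        final = wt.trajectory.final
        if target is None:
            target = grid.integrate(final.rho_M)
        if rho0 is None:
            rho0 = mean_intramedullary_density(final, base.mu)
    return float(target), float(rho0)


def _run_sphere(name: str, grid: Grid, rng_seed: int, base: ModelParams,
                overrides: dict[str, Any], t_max: float, dt_max: float,
                n_snapshots: int, extra: dict[str, Any]) -> ExperimentResult:
    target, rho0 = _sphere_reference(grid, rng_seed, base, t_max, dt_max, extra)
    morph = FixedMorphology("sphere", target, interior_density=rho0)
    state0 = fixed_morphology_state(grid, morph)

    frozen = base.with_overrides(**{**overrides, "medulla_frozen": True})
    if name == "sphere_krec":
        traj, metrics = _run(state0, frozen, grid, t_max, dt_max, n_snapshots)
        return ExperimentResult(name, frozen, grid, rng_seed, traj, metrics)

    t_switch = float(extra.get("t_switch", 3000.0))
    t_end = float(extra.get("t_end", 6000.0))
    traj1 = integrate(state0, t_switch, frozen, grid,
                      output_schedule=_snapshot_schedule(t_switch, n_snapshots),
                      dt_max=dt_max)
    live = base.with_overrides(**{**overrides, "medulla_frozen": False})
    traj2 = integrate(traj1.final, t_end - t_switch, live, grid,
                      output_schedule=_snapshot_schedule(t_end - t_switch, n_snapshots),
                      dt_max=dt_max)
    traj = Trajectory(live, grid, traj1.snapshots + traj2.snapshots[1:],
                      traj1.diagnostics + traj2.diagnostics[1:])
    metrics = _metrics_frame(traj, live, grid)
    metrics["phase"] = np.where(metrics["t"] <= t_switch, "frozen", "dynamic")
    return ExperimentResult(name, live, grid, rng_seed, traj, metrics)


def _run_localization_staged(name: str, grid: Grid, rng_seed: int,
                             base: ModelParams, overrides: dict[str, Any],
                             t_max: float, dt_max: float, n_snapshots: int,
                             extra: dict[str, Any]) -> ExperimentResult:
    """Localization metrics measured on a developed cortex-medulla pattern.

    Stage 1 grows the pattern from seeds with the base model (Eqs. without
    the exit term); stage 2 switches on the thymus-exit term and the
    tolerant species (starting from zero) and equilibrates for ``t_ext``
    (default 800 h, several exit times), after which the thymocyte
    localization statistics are read off.  This protocol is required in
    small 3D boxes where the exit-capped thymocyte density cannot nucleate
    the medulla from seeds.
    """
    chemo = not name.endswith("no_chemotaxis")
    grow = base.with_overrides(chemotaxis_on=chemo)
    spec = SeedSpec(n_seeds=extra.get("n_seeds", default_seed_count(grid)),
                    width=extra.get("seed_width", 60.0),
                    amplitude=grow.K_cap, rng_seed=rng_seed)
    traj1 = integrate(seeded_initial_state(grid, spec), t_max, grow, grid,
                      output_schedule=_snapshot_schedule(t_max, n_snapshots),
                      dt_max=dt_max)
    ext = base.with_overrides(**{**overrides, "chemotaxis_on": chemo,
                                 "exit_term_on": True, "tolerant_on": True})
    t_ext = float(extra.get("t_ext", 800.0))
    state = traj1.final.copy()
    state.rho_T0 = np.zeros(grid.shape)
    traj2 = integrate(state, t_ext, ext, grid,
                      output_schedule=_snapshot_schedule(t_ext, n_snapshots),
                      dt_max=dt_max)
    traj = Trajectory(ext, grid, traj1.snapshots + traj2.snapshots[1:],
                      traj1.diagnostics + traj2.diagnostics[1:])
    metrics = _metrics_frame(traj, ext, grid)
    metrics["phase"] = np.where(metrics["t"] <= t_max, "growth", "extended")
    return ExperimentResult(name, ext, grid, rng_seed, traj, metrics)


def _run_lamellae(grid: Grid, rng_seed: int, base: ModelParams,
                  overrides: dict[str, Any], t_max: float, dt_max: float,
                  extra: dict[str, Any]) -> ExperimentResult:
    periods: Sequence[float] = extra.get("periods") or (200.0, 375.0, 750.0, 1500.0)
    target, rho0 = _sphere_reference(grid, rng_seed, base, t_max, dt_max, extra)
    frozen = base.with_overrides(**{**overrides, "medulla_frozen": True})
    rows = []
    traj = None
    for P in periods:
        morph = FixedMorphology("lamellae", target, interior_density=rho0, period=float(P))
        state0 = fixed_morphology_state(grid, morph)
        traj, _ = _run(state0, frozen, grid, t_max, dt_max, n_snapshots=2)
        final = traj.final
        rows.append({
            "period": float(P),
            "k_rec": effective_recognition_rate(final, frozen),
            "total_mTEC": grid.integrate(final.rho_M),
        })
    table = pd.DataFrame(rows)
    return ExperimentResult("lamellae_krec", frozen, grid, rng_seed, traj,
                            pd.DataFrame(), table=table)


def pd_scan(grid: Grid, rng_seed: int = 0,
            base_params: ModelParams | None = None,
            p_factors: Sequence[float] | None = None,
            d_factors: Sequence[float] | None = None,
            t_max: float = 1000.0, dt_max: float = 0.1,
            n_seeds: int | None = None) -> pd.DataFrame:
    """Morphology metrics over a (p, d) multiplier grid (shared seed layout)."""
    base = base_params if base_params is not None else ModelParams()
    p_factors = tuple(p_factors) if p_factors is not None else (0.25, 0.5, 1.0, 2.0, 4.0)
    d_factors = tuple(d_factors) if d_factors is not None else (0.25, 0.5, 1.0, 2.0, 4.0)
    count = n_seeds if n_seeds is not None else default_seed_count(grid)
    rows = []
    for fp in p_factors:
        for fd in d_factors:
            params = base.with_overrides(p=base.p * fp, d=base.d * fd)
            spec = SeedSpec(n_seeds=count, amplitude=params.K_cap, rng_seed=rng_seed)
            state0 = seeded_initial_state(grid, spec)
            traj = integrate(state0, t_max, params, grid, dt_max=dt_max)
            m = compute_metrics(traj.final, params, grid)
            phi_pred, p_over_d = predicted_volume_fraction(params)
            rows.append({
                "p_factor": fp, "d_factor": fd, "p": params.p, "d": params.d,
                "phi_M": m.phi_M, "ell": m.ell, "k_rec": m.k_rec,
                "phi_pred": phi_pred, "p_over_d": p_over_d,
            })
    return pd.DataFrame(rows)
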