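"""Linear stability analysis of uniform steady states.

Perturbing a uniform state with a Fourier mode e^{iq·x} turns the
linearized PDE into a 4×4 eigenvalue problem per wavenumber q: the
reaction Jacobian, minus diffusive damping q²·diag(D), plus the
chemotaxis coupling from the chemokine column into the two motile
thymocyte rows (+ρ̄ T χ(ρ̄C) q², the aggregation feedback).

Two reduced variants isolate the pattern-forming mechanisms:

* ``no_chemotaxis`` — taxis strength set to zero; any remaining
  instability is the growth-induced (Turing-type) one rooted in the
  mTEC–activated-thymocyte positive feedback.
* ``no_bistability`` — mTEC proliferation made linear in ρM
  (k_b ρT* M̄ (1−ρM/K) with M̄ the reference steady state), which keeps
  the steady state but removes the ρM² self-catalysis responsible for
  the fold in the mTEC dynamics; any remaining instability is the
  chemotaxis-driven (Keller–Segel) one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .fields import HomogeneousState
from .model import chemotactic_sensitivity, homogeneous_steady_state, reaction_terms
from .fields import FieldState
from .params import ModelParams

VARIANTS = ("full", "no_chemotaxis", "no_bistability")


class NotSteadyError(ValueError):
    """The reference state is not a steady state of the chosen variant."""


def _check_steady(state: HomogeneousState, params: ModelParams,
                  rel_tol: float = 1e-6) -> None:
    arrs = {k: np.array([[v]]) for k, v in {
        "rho_T": state.rho_T, "rho_Tstar": state.rho_Tstar,
        "rho_M": state.rho_M, "rho_C": state.rho_C}.items()}
    fs = FieldState(0.0, arrs["rho_T"], arrs["rho_Tstar"], arrs["rho_M"], arrs["rho_C"])
    rates = reaction_terms(fs, params)
    scales = {
        "rho_T": params.p,
        "rho_Tstar": params.d * max(state.rho_Tstar, params.p / params.d),
        "rho_M": params.k_m * max(state.rho_M, params.mu),
        "rho_C": params.k_c * max(state.rho_C, params.k_e * params.mu / params.k_c),
    }
    for name, rate in rates.items():
        if abs(float(rate[0, 0])) > rel_tol * scales[name]:
            raise NotSteadyError(
                f"reference state is not steady: residual in {name} = {float(rate[0,0]):.3g}"
            )


def _phi_prime(rho_M: float, mu: float) -> float:
    r = rho_M / mu
    return -2.0 * r / mu / (1.0 + r * r) ** 2


def jacobian(q: float, state: HomogeneousState, params: ModelParams,
             model_variant: str = "full", check_steady: bool = True) -> np.ndarray:
    """4×4 stability matrix at wavenumber q (rows/cols: ρT, ρT*, ρM, ρC)."""
    if model_variant not in VARIANTS:
        raise ValueError(f"unknown variant {model_variant!r}; choose from {VARIANTS}")
    if q < 0:
        raise ValueError("q must be non-negative")
    if check_steady:
        _check_steady(state, params)
    P = params
    T, Ts, M, C = state.rho_T, state.rho_Tstar, state.rho_M, state.rho_C
    kex = P.k_ex if P.exit_term_on else 0.0

    J = np.zeros((4, 4))
    # reactions
    J[0, 0] = -P.k_r * M - kex
    J[0, 2] = -P.k_r * T + P.p * _phi_prime(M, P.mu)
    J[1, 0] = P.k_r * M
    J[1, 1] = -P.d
    J[1, 2] = P.k_r * T
    if model_variant == "no_bistability":
        J[2, 1] = P.k_b * M * (1.0 - M / P.K_cap)
        J[2, 2] = -P.k_b * Ts * M / P.K_cap - P.k_m
    else:
        J[2, 1] = P.k_b * M * (1.0 - M / P.K_cap)
        J[2, 2] = P.k_b * Ts * (1.0 - 2.0 * M / P.K_cap) - P.k_m
    J[3, 2] = P.k_e
    J[3, 3] = -P.k_c

    # diffusive damping
    q2 = q * q
    J[0, 0] -= P.D_T * q2
    J[1, 1] -= P.D_T * q2
    J[2, 2] -= P.D_M * q2
    J[3, 3] -= P.D_C * q2

    # chemotaxis coupling (aggregation feedback from δρC into the motile rows)
    taxis = 0.0 if model_variant == "no_chemotaxis" else P.taxis
    if taxis != 0.0:
        chi = chemotactic_sensitivity(C, P.K_offon)
        J[0, 3] += T * taxis * chi * q2
        J[1, 3] += Ts * taxis * chi * q2
    return J


def growth_rate(q: float, state: HomogeneousState, params: ModelParams,
                model_variant: str = "full") -> float:
    """Largest real part of the eigenvalues at wavenumber q (h⁻¹)."""
    J = jacobian(q, state, params, model_variant, check_steady=False)
    return float(np.linalg.eigvals(J).real.max())


@dataclass
class DispersionResult:
    """Growth rates λ(q) of the linearized system."""

    q: np.ndarray
    lambda_max: np.ndarray
    q_star: float
    lambda_star: float
    unstable: bool
    variant: str
    state: HomogeneousState | None
    no_steady_state: bool = False

    @property
    def fastest_wavelength(self) -> float:
        """2π/q* of the fastest-growing mode, μm."""
        return 2.0 * np.pi / self.q_star if self.q_star > 0 else np.inf


def default_q_grid(L: float = 3000.0, n_ref: int = 256, num: int = 200) -> np.ndarray:
    """200 log-spaced wavenumbers from the box mode 2π/L to π/dx."""
    return np.geomspace(2.0 * np.pi / L, np.pi / (L / n_ref), num)


def dispersion_relation(params: ModelParams, q_grid: np.ndarray | None = None,
                        model_variant: str = "full",
                        state: HomogeneousState | None = None) -> DispersionResult:
    """λ_max(q) over a wavenumber grid, with golden-section refinement of q*.

    Uses the nontrivial uniform branch with the largest ρM unless an
    explicit reference state is passed.  Returns a structured
    "no pattern state" result when no nontrivial branch exists.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if state is None:
        state = homogeneous_steady_state(params).patterned_branch
    if state is None:
        nan = np.full_like(q_grid, np.nan)
        return DispersionResult(q_grid, nan, 0.0, np.nan, False, model_variant,
                                None, no_steady_state=True)
    _check_steady(state, params)

    lam = np.array([growth_rate(q, state, params, model_variant) for q in q_grid])

    i = int(np.argmax(lam))
    lo = q_grid[max(i - 1, 0)]
    hi = q_grid[min(i + 1, len(q_grid) - 1)]
    q_star, lam_star = q_grid[i], lam[i]
    if hi > lo:
        res = minimize_scalar(
            lambda q: -growth_rate(q, state, params, model_variant),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6 * max(q_grid[-1], 1.0)})
        if -res.fun >= lam_star:
            q_star, lam_star = float(res.x), float(-res.fun)

    positive = lam[q_grid > 0]
    unstable = bool(positive.max() > 0) if positive.size else False
    if lam_star > 0 and q_star > 0:
        unstable = True
    return DispersionResult(q_grid, lam, q_star, lam_star, unstable, model_variant, state)


@dataclass
class InstabilityMap:
    """Instability classification over a (k_b, T) parameter scan.

    Boolean matrices are indexed ``[i_kb, j_T]``.  Classification values:
    ``stable``, ``growth`` (unstable already at T=0), ``chemotaxis``
    (stable at T=0, unstable with chemotaxis) and ``mixed`` (unstable at
    T=0 and in the bistability-free variant).
    """

    kb_values: np.ndarray
    T_values: np.ndarray
    unstable_full: np.ndarray
    unstable_T0: np.ndarray           # per k_b (chemotaxis-independent band)
    unstable_no_bistability: np.ndarray
    classification: np.ndarray


def instability_map(params: ModelParams, kb_values: np.ndarray,
                    T_values: np.ndarray,
                    q_grid: np.ndarray | None = None) -> InstabilityMap:
    """Scan the (k_b, T) plane for linear instability of the uniform state."""
    kb_values = np.asarray(kb_values, dtype=float)
    T_values = np.asarray(T_values, dtype=float)
    nk, nt = len(kb_values), len(T_values)
    full = np.zeros((nk, nt), dtype=bool)
    nobi = np.zeros((nk, nt), dtype=bool)
    t0 = np.zeros(nk, dtype=bool)
    cls = np.full((nk, nt), "stable", dtype=object)

    for i, kb in enumerate(kb_values):
        p_kb = params.with_overrides(k_b=float(kb))
        state = homogeneous_steady_state(p_kb).patterned_branch
        if state is None:
            continue
        t0[i] = dispersion_relation(p_kb, q_grid, "no_chemotaxis", state).unstable
        for j, T in enumerate(T_values):
            p_ij = p_kb.with_overrides(T_chi=float(T), chemotaxis_on=True)
            full[i, j] = dispersion_relation(p_ij, q_grid, "full", state).unstable
            nobi[i, j] = dispersion_relation(p_ij, q_grid, "no_bistability", state).unstable
            if full[i, j]:
                if t0[i] and nobi[i, j]:
                    cls[i, j] = "mixed"
                elif t0[i]:
                    cls[i, j] = "growth"
                else:
                    cls[i, j] = "chemotaxis"
    return InstabilityMap(kb_values, T_values, full, t0, nobi, cls)
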