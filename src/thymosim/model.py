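"""Right-hand sides of the thymic cross-talk equations.

The model couples self-reactive thymocytes ρT, activated thymocytes ρT*,
mTECs ρM and a chemokine ρC on a periodic domain:

    ∂t ρT  = D_T ∇²ρT  − ∇·(ρT v_C)  − k_r ρT ρM + p φ(ρM) [− k_ex ρT]
    ∂t ρT* = D_T ∇²ρT* − ∇·(ρT* v_C) + k_r ρT ρM − d ρT*
    ∂t ρM  = D_M ∇²ρM  + k_b ρT* ρM (1 − ρM/K) − k_m ρM
    ∂t ρC  = D_C ∇²ρC  + k_e ρM − k_c ρC
    ∂t ρT0 = D_T ∇²ρT0 − ∇·(ρT0 v_C) + p_T0 φ(ρM) − k_ex ρT0

with the cortex indicator φ(ρM) = 1/(1 + (ρM/μ)²), the receptor-kinetics
chemotactic sensitivity χ(ρC) = K/(K + ρC)² and the drift velocity
v_C = T χ(ρC) ∇ρC.  The ρT0 (self-tolerant) equation and the −k_ex ρT
exit term are only active in the extended localization model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .fields import FieldState, HomogeneousState
from .grid import Grid
from .params import ModelParams, InvalidParameterError


class NumericalFailureError(RuntimeError):
    """A derivative or step produced non-finite values."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


# ---------------------------------------------------------------------------
# local (pointwise) model functions
# ---------------------------------------------------------------------------

def indicator_phi(rho_M, mu: float):
    """Smooth cortex indicator φ(ρM) = 1/(1 + (ρM/μ)²) ∈ (0, 1].

    Equals ~1 in the cortex (ρM ≪ μ) and decays to ~0 deep in the medulla.
    """
    if mu <= 0:
        raise InvalidParameterError(f"mu must be positive, got {mu}")
    r = np.asarray(rho_M, dtype=float) / mu
    out = 1.0 / (1.0 + r * r)
    return out if out.ndim else float(out)


def chemotactic_sensitivity(rho_C, K_offon: float):
    """Receptor-kinetics sensitivity χ(ρC) = K/(K + ρC)², in nM⁻¹.

    Maximal (1/K) at vanishing chemokine; decreasing with receptor
    saturation at high concentration.
    """
    if K_offon <= 0:
        raise InvalidParameterError(f"K_offon must be positive, got {K_offon}")
    c = np.asarray(rho_C, dtype=float)
    if c.min() < 0:
        raise ValueError("chemokine concentration must be non-negative")
    out = K_offon / (K_offon + c) ** 2
    return out if out.ndim else float(out)


def drift_velocity(rho_C: np.ndarray, params: ModelParams, grid: Grid) -> list[np.ndarray]:
    """Chemotactic drift v_C = T χ(ρC) ∇ρC (μm/h), one array per axis.

    Identically zero when chemotaxis is switched off.
    """
    grid.check_field(rho_C, "rho_C")
    if params.taxis == 0.0:
        return [np.zeros(grid.shape) for _ in range(grid.ndim)]
    chi = chemotactic_sensitivity(rho_C, params.K_offon)
    pref = params.taxis * chi
    return [pref * g for g in grid.gradient(rho_C)]


def reaction_terms(state: FieldState, params: ModelParams) -> dict[str, np.ndarray]:
    """Local source/sink terms for every active field (no transport)."""
    P = params
    phi = indicator_phi(state.rho_M, P.mu)
    act = P.k_r * state.rho_T * state.rho_M
    out: dict[str, np.ndarray] = {}
    f_T = -act + P.p * phi
    if P.exit_term_on:
        f_T = f_T - P.k_ex * state.rho_T
    out["rho_T"] = f_T
    out["rho_Tstar"] = act - P.d * state.rho_Tstar
    if P.medulla_frozen:
        out["rho_M"] = np.zeros_like(state.rho_M)
    else:
        out["rho_M"] = (
            P.k_b * state.rho_Tstar * state.rho_M * (1.0 - state.rho_M / P.K_cap)
            - P.k_m * state.rho_M
        )
    out["rho_C"] = P.k_e * state.rho_M - P.k_c * state.rho_C
    if P.tolerant_on and state.rho_T0 is not None:
        out["rho_T0"] = P.p_tolerant * phi - P.k_ex * state.rho_T0
    return out


#: diffusivity of each field (attribute name on ModelParams)
DIFFUSIVITY_OF = {
    "rho_T": "D_T", "rho_Tstar": "D_T", "rho_T0": "D_T",
    "rho_M": "D_M", "rho_C": "D_C",
}
#: fields advected by the chemotactic drift
ADVECTED = ("rho_T", "rho_Tstar", "rho_T0")


def rhs(state: FieldState, params: ModelParams, grid: Grid) -> dict[str, np.ndarray]:
    """Full time derivative of every active field: reactions + transport."""
    state.validate(grid)
    out = reaction_terms(state, params)
    v = drift_velocity(state.rho_C, params, grid)
    advecting = params.taxis != 0.0
    for name in out:
        arr = getattr(state, name)
        if name == "rho_M" and params.medulla_frozen:
            continue
        D = getattr(params, DIFFUSIVITY_OF[name])
        out[name] = out[name] + D * grid.laplacian(arr)
        if name in ADVECTED and advecting:
            out[name] = out[name] - grid.divergence([arr * vi for vi in v])
    for name, arr in out.items():
        if not np.isfinite(arr).all():
            raise NumericalFailureError(f"non-finite time derivative in {name}", field=name)
    return out


# ---------------------------------------------------------------------------
# homogeneous steady states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyStates:
    """Spatially uniform fixed points of the reaction system.

    ``trivial`` is the mTEC-free branch (finite only with the exit term;
    otherwise ρT grows without bound and ``trivial_note`` explains why).
    ``nontrivial`` lists all roots with ρM ∈ (0, K), largest ρM last.
    """

    trivial: HomogeneousState | None
    trivial_note: str
    nontrivial: tuple[HomogeneousState, ...]

    @property
    def patterned_branch(self) -> HomogeneousState | None:
        """The branch used for stability analysis: largest nontrivial ρM."""
        return self.nontrivial[-1] if self.nontrivial else None


def _steady_residual(rho_M: np.ndarray | float, params: ModelParams):
    """Residual whose roots in (0, K) are the nontrivial uniform states.

    Without the exit term this is p φ(ρM) k_b (1−ρM/K) − d k_m; with it the
    production is shared between activation and thymus exit.
    """
    P = params
    phi = indicator_phi(rho_M, P.mu)
    frac = 1.0
    if P.exit_term_on:
        frac = P.k_r * np.asarray(rho_M) / (P.k_r * np.asarray(rho_M) + P.k_ex)
    return P.p * phi * frac * P.k_b * (1.0 - np.asarray(rho_M) / P.K_cap) - P.d * P.k_m


def _complete_state(rho_M: float, params: ModelParams) -> HomogeneousState:
    P = params
    rho_Tstar = P.k_m / (P.k_b * (1.0 - rho_M / P.K_cap))
    if P.exit_term_on:
        rho_T = P.p * indicator_phi(rho_M, P.mu) / (P.k_r * rho_M + P.k_ex)
    else:
        rho_T = P.d * rho_Tstar / (P.k_r * rho_M)
    rho_C = P.k_e * rho_M / P.k_c
    rho_T0 = P.p_tolerant * indicator_phi(rho_M, P.mu) / P.k_ex if P.tolerant_on else 0.0
    return HomogeneousState(rho_T, rho_Tstar, rho_M, rho_C, rho_T0)


def homogeneous_steady_state(params: ModelParams, n_scan: int = 4096) -> SteadyStates:
    """Find all non-negative spatially uniform steady states.

    Nontrivial roots are bracketed by a dense scan of the balance residual
    over ρM ∈ (0, K) and polished with Brent's method.
    """
    P = params
    if P.exit_term_on:
        trivial = HomogeneousState(P.p / P.k_ex, 0.0, 0.0, 0.0,
                                   P.p_tolerant / P.k_ex if P.tolerant_on else 0.0)
        note = "mTEC-free branch with exit term: rho_T = p/k_ex"
    else:
        trivial = None
        note = ("no finite trivial state: without the exit term the mTEC-free "
                "branch has constant thymocyte production and no sink")

    eps = 1e-9 * P.K_cap
    ms = np.linspace(eps, P.K_cap * (1.0 - 1e-9), n_scan)
    res = _steady_residual(ms, P)
    roots: list[float] = []
    sign = np.sign(res)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    for i in idx:
        try:
            r = brentq(lambda m: _steady_residual(m, P), ms[i], ms[i + 1],
                       xtol=1e-14 * P.K_cap, rtol=1e-14)
        except ValueError:  # pragma: no cover - degenerate bracket
            continue
        roots.append(float(r))
    roots.sort()
    return SteadyStates(trivial, note, tuple(_complete_state(m, P) for m in roots))
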