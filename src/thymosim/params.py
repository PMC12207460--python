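"""Model parameters for the spatial thymic cross-talk model.

The model couples four density fields on a periodic domain:

* ``rho_T``      -- self-reactive (SP CD4) thymocytes, cells/μm³
* ``rho_Tstar``  -- activated (antigen-recognized) thymocytes, cells/μm³
* ``rho_M``      -- medullary thymic epithelial cells (mTECs), cells/μm³
* ``rho_C``      -- effective medullary chemokine concentration, nM
* ``rho_T0``     -- (optional) self-tolerant thymocytes, cells/μm³

Units used throughout the package: lengths in μm, times in hours, cell
densities in μm⁻³ and chemokine concentration in nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Any


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the model's constraints."""


@dataclass(frozen=True)
class ModelParams:
    """Rate and transport constants of the thymic cross-talk equations.

    Defaults are the wild-type (wt) parameter set.  The chemokine emission
    coefficient ``k_e`` is calibrated so that a medulla at carrying capacity
    sustains a local chemokine concentration equal to the receptor binding
    constant, ``k_e * K_cap / k_c = K_offon``, which places the chemokine
    receptor at half saturation inside mature medullary tissue (the regime
    of maximal chemotactic dynamic range).
    """

    # transport (μm²/h)
    D_C: float = 2.34e4     # chemokine diffusivity
    D_T: float = 2.4e4      # thymocyte random motility
    D_M: float = 3.0        # mTEC random motility
    T_chi: float = 1e5      # chemotaxis (taxis) strength, μm²/h per (χ·nM)

    # receptor kinetics
    K_offon: float = 5.0    # receptor binding constant, nM

    # thymocyte kinetics
    p: float = 2.5e-6       # SP thymocyte production rate, μm⁻³ h⁻¹
    mu: float = 1e-4        # mTEC density scale of the cortex indicator, μm⁻³
    d: float = 1.0          # activated-thymocyte deletion rate, h⁻¹
    k_r: float = 1.5e3      # activation (recognition) rate coefficient, μm³ h⁻¹

    # mTEC kinetics
    k_b: float = 3e3        # mTEC birth rate coefficient, μm³ h⁻¹
    K_cap: float = 7.5e-4   # mTEC carrying capacity, μm⁻³
    k_m: float = 5e-3       # mTEC decay rate, h⁻¹

    # chemokine kinetics
    k_e: float = 5.0 * 10.0 / 7.5e-4   # emission coefficient, nM μm³ h⁻¹
    k_c: float = 10.0       # chemokine decay rate, h⁻¹

    # extended (localization) model
    p_T0: float | None = None          # tolerant production rate; None -> p
    k_ex: float = 1.0 / 120.0          # thymus-exit rate, h⁻¹ (5-day dwell)

    # switches
    chemotaxis_on: bool = True
    medulla_frozen: bool = False
    exit_term_on: bool = False
    tolerant_on: bool = False

    def __post_init__(self) -> None:
        rates = {
            "D_C": self.D_C, "D_T": self.D_T, "D_M": self.D_M,
            "T_chi": self.T_chi, "K_offon": self.K_offon, "p": self.p,
            "mu": self.mu, "d": self.d, "k_r": self.k_r, "k_b": self.k_b,
            "K_cap": self.K_cap, "k_m": self.k_m, "k_e": self.k_e,
            "k_c": self.k_c, "k_ex": self.k_ex,
        }
        for name, value in rates.items():
            if not (value >= 0.0):
                raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")
        if self.mu <= 0:
            raise InvalidParameterError("mu must be positive")
        if self.K_offon <= 0:
            raise InvalidParameterError("K_offon must be positive")
        if not self.K_cap > self.mu:
            raise InvalidParameterError(
                f"carrying capacity K_cap={self.K_cap} must exceed mu={self.mu}"
            )
        if self.p_T0 is not None and self.p_T0 < 0:
            raise InvalidParameterError("p_T0 must be >= 0")

    @property
    def p_tolerant(self) -> float:
        """Tolerant-thymocyte production rate (defaults to ``p``)."""
        return self.p if self.p_T0 is None else self.p_T0

    @property
    def taxis(self) -> float:
        """Effective taxis strength: 0 when chemotaxis is switched off."""
        return self.T_chi if self.chemotaxis_on else 0.0

    def with_overrides(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        unknown = set(kwargs) - set(asdict(self))
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s): {sorted(unknown)}"
            )
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


#: Wild-type parameter set (module-level convenience instance).
WT = ModelParams()
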