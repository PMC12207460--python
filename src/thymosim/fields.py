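"""Density-field containers for the cross-talk model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .grid import Grid, DimensionError


class FieldValidationError(ValueError):
    """A field state violates non-negativity / finiteness / shape constraints."""


#: canonical field order used throughout the package
FIELD_NAMES = ("rho_T", "rho_Tstar", "rho_M", "rho_C", "rho_T0")


@dataclass
class FieldState:
    """The model's density fields at one time.

    ``rho_T``/``rho_Tstar``/``rho_M`` are cell number densities (μm⁻³),
    ``rho_C`` a chemokine concentration (nM).  ``rho_T0`` (tolerant
    thymocytes) is present only in the extended localization model.
    """

    t: float
    rho_T: np.ndarray
    rho_Tstar: np.ndarray
    rho_M: np.ndarray
    rho_C: np.ndarray
    rho_T0: np.ndarray | None = None

    @classmethod
    def zeros(cls, grid: Grid, t: float = 0.0, tolerant: bool = False) -> "FieldState":
        z = lambda: np.zeros(grid.shape)
        return cls(t, z(), z(), z(), z(), z() if tolerant else None)

    @property
    def has_tolerant(self) -> bool:
        return self.rho_T0 is not None

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in FIELD_NAMES:
            arr = getattr(self, name)
            if arr is not None:
                yield name, arr

    def validate(self, grid: Grid | None = None) -> None:
        shapes = {arr.shape for _, arr in self.items()}
        if len(shapes) != 1:
            raise FieldValidationError(f"fields have mismatched shapes: {shapes}")
        if grid is not None and shapes.pop() != grid.shape:
            raise DimensionError("field shape does not match grid")
        for name, arr in self.items():
            if not np.isfinite(arr).all():
                raise FieldValidationError(f"{name} contains non-finite values")
            if arr.min() < 0:
                raise FieldValidationError(f"{name} contains negative values")

    def copy(self) -> "FieldState":
        return FieldState(
            self.t,
            *(arr.copy() for arr in (self.rho_T, self.rho_Tstar, self.rho_M, self.rho_C)),
            self.rho_T0.copy() if self.rho_T0 is not None else None,
        )


@dataclass(frozen=True)
class HomogeneousState:
    """A spatially uniform state of the four core densities."""

    rho_T: float
    rho_Tstar: float
    rho_M: float
    rho_C: float
    rho_T0: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_T, self.rho_Tstar, self.rho_M, self.rho_C])

    def to_fields(self, grid: Grid, t: float = 0.0, tolerant: bool = False) -> FieldState:
        full = lambda v: np.full(grid.shape, float(v))
        return FieldState(
            t, full(self.rho_T), full(self.rho_Tstar), full(self.rho_M),
            full(self.rho_C), full(self.rho_T0) if tolerant else None,
        )
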