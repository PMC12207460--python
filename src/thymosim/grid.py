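"""Periodic lattice geometry and spectral bookkeeping.

All spatial operators (gradient, Laplacian, flux divergence) act through
the real FFT on a uniform periodic grid, so fields are differentiated to
spectral accuracy.  The grid precomputes the wavenumber symbols and the
2/3-rule dealiasing mask used for the quadratic chemotaxis flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft


class GridResolutionWarning(UserWarning):
    """Grid spacing does not resolve the shortest intrinsic length."""


class DimensionError(ValueError):
    """Field shape does not match the grid."""


@dataclass
class Grid:
    """Uniform periodic grid in 2 or 3 dimensions.

    Parameters
    ----------
    ndim : 2 or 3
    n : points per side
    L : physical side length, μm
    """

    ndim: int
    n: int
    L: float
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {self.ndim}")
        if self.n < 16:
            raise ValueError(f"n must be >= 16, got {self.n}")
        if self.L <= 0:
            raise ValueError("L must be positive")
        self.dx = self.L / self.n

        n, L = self.n, self.L
        k1 = 2.0 * np.pi * sfft.fftfreq(n, d=self.dx)
        k1r = 2.0 * np.pi * sfft.rfftfreq(n, d=self.dx)
        # wavevector components broadcast over the rfftn output shape
        shape_r = (n,) * (self.ndim - 1) + (n // 2 + 1,)
        self.shape = (n,) * self.ndim
        self.shape_r = shape_r
        ks = []
        for axis in range(self.ndim):
            kax = k1r if axis == self.ndim - 1 else k1
            sl = [None] * self.ndim
            sl[axis] = slice(None)
            ks.append(kax[tuple(sl)])
        self.k = ks                                    # broadcastable components
        self.k2 = sum(np.broadcast_to(ki**2, shape_r).copy() for ki in ks)
        # 2/3-rule dealiasing mask for quadratic nonlinearities
        kmax = k1r.max()
        mask = np.ones(shape_r, dtype=bool)
        for ki in ks:
            mask &= np.broadcast_to(np.abs(ki) <= (2.0 / 3.0) * kmax, shape_r)
        self.dealias = mask

    # -- constructors ------------------------------------------------------

    @classmethod
    def make(cls, ndim: int, n: int, L: float,
             D_C: float = 2.34e4, k_c: float = 10.0) -> "Grid":
        """Build a grid, warning when dx exceeds half the chemokine decay
        length sqrt(D_C/k_c) (the shortest intrinsic model length)."""
        g = cls(ndim, n, L)
        if k_c > 0:
            dx_max = 0.5 * np.sqrt(D_C / k_c)
            if g.dx > dx_max:
                warnings.warn(
                    f"dx = {g.dx:.3g} μm exceeds 0.5·sqrt(D_C/k_c) = "
                    f"{dx_max:.3g} μm; chemokine gradients under-resolved",
                    GridResolutionWarning,
                    stacklevel=2,
                )
        return g

    # -- bookkeeping -------------------------------------------------------

    @property
    def volume(self) -> float:
        """Domain volume (area in 2D), μm^ndim."""
        return self.L**self.ndim

    @property
    def cell_volume(self) -> float:
        return self.dx**self.ndim

    def check_field(self, f: np.ndarray, name: str = "field") -> None:
        if f.shape != self.shape:
            raise DimensionError(
                f"{name} has shape {f.shape}, grid expects {self.shape}"
            )

    def coords(self) -> list[np.ndarray]:
        """Cell-center coordinate arrays (1D, per axis), μm."""
        x = (np.arange(self.n) + 0.5) * self.dx
        return [x] * self.ndim

    def meshgrid(self) -> list[np.ndarray]:
        return list(np.meshgrid(*self.coords(), indexing="ij"))

    # -- spectral operators ------------------------------------------------

    def fft(self, f: np.ndarray) -> np.ndarray:
        return sfft.rfftn(f)

    def ifft(self, fh: np.ndarray) -> np.ndarray:
        return sfft.irfftn(fh, s=self.shape)

    def gradient(self, f: np.ndarray) -> list[np.ndarray]:
        """Spectral gradient, one array per axis."""
        self.check_field(f)
        fh = self.fft(f)
        return [self.ifft(1j * ki * fh) for ki in self.k]

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        self.check_field(f)
        return self.ifft(-self.k2 * self.fft(f))

    def divergence(self, comps: list[np.ndarray]) -> np.ndarray:
        """Spectral divergence of a vector field."""
        out = np.zeros(self.shape_r, dtype=complex)
        for ki, c in zip(self.k, comps):
            self.check_field(c)
            out += 1j * ki * self.fft(c)
        return self.ifft(out)

    def integrate(self, f: np.ndarray) -> float:
        """Domain integral by the trapezoid-exact periodic quadrature."""
        self.check_field(f)
        return float(f.sum() * self.cell_volume)

    def mean(self, f: np.ndarray) -> float:
        return float(f.mean())


def make_grid(ndim: int, n: int, L: float, **kwargs) -> Grid:
    """Functional alias for :meth:`Grid.make`."""
    return Grid.make(ndim, n, L, **kwargs)
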