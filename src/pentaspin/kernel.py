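"""Powder-averaged dipolar kernel for DEER/PELDOR inversion.

For an isotropic orientation distribution the intramolecular form factor of a
spin pair at distance r is

    K(t, r) = \\int_0^1 cos[ omega_dd(r) (1 - 3 x^2) t ] dx,

with omega_dd = 2 pi * D / r^3 and D ~= 52.04 MHz nm^3 the dipolar constant of
two free electron spins. The integral has the closed Fresnel form

    K = sqrt(pi / (6 phi)) [ cos(phi) C(z) + sin(phi) S(z) ],
    phi = omega_dd t,  z = sqrt(6 phi / pi),

used here column-by-column (t = 0 and tiny phases handled by series limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import fresnel

from .constants import DIPOLAR_MHZ_NM3
from .io import PipelineError

__all__ = ["DipolarKernel", "build_kernel", "dipolar_frequency_mhz"]


def dipolar_frequency_mhz(r_nm: float) -> float:
    """Perpendicular dipolar frequency nu_perp = D / r^3 in MHz."""
    return DIPOLAR_MHZ_NM3 / float(r_nm) ** 3


def _fresnel_kernel(phi: np.ndarray) -> np.ndarray:
    """Powder-average integral as a function of the phase phi = omega*t >= 0."""
    phi = np.asarray(phi, dtype=float)
    out = np.ones_like(phi)
    big = phi > 1e-9
    ph = phi[big]
    z = np.sqrt(6.0 * ph / np.pi)
    s, c = fresnel(z)
    out[big] = np.sqrt(np.pi / (6.0 * ph)) * (np.cos(ph) * c + np.sin(ph) * s)
    return out


@dataclass
class DipolarKernel:
    """Kernel matrix K[t, r] with its time (µs) and distance (nm) grids."""

    matrix: np.ndarray
    t_grid: np.ndarray
    r_grid: np.ndarray

    @property
    def dr(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])


def build_kernel(t_grid: np.ndarray, r_grid: np.ndarray) -> DipolarKernel:
    """Build the powder-averaged dipolar kernel on the given grids.

    ``t_grid`` in microseconds (non-negative), ``r_grid`` in nanometres
    (strictly positive); both strictly increasing.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    if t_grid.size == 0 or r_grid.size == 0:
        raise PipelineError("kernel grids must be non-empty")
    if np.any(np.diff(t_grid) <= 0) or (r_grid.size > 1 and np.any(np.diff(r_grid) <= 0)):
        raise PipelineError("kernel grids must be strictly increasing")
    if np.any(r_grid <= 0):
        raise PipelineError("distance grid must be strictly positive")
    if np.any(t_grid < 0):
        raise PipelineError("time grid must be non-negative")
    # phase in rad: 2 pi * (MHz) * (µs)
    omega = 2.0 * np.pi * DIPOLAR_MHZ_NM3 / r_grid**3
    phi = np.abs(t_grid[:, None] * omega[None, :])
    return DipolarKernel(matrix=_fresnel_kernel(phi), t_grid=t_grid, r_grid=r_grid)
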