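"""Feynman–Hibbs effective potentials.

The variationally optimal classical potential accounting for nuclear
quantum effects is the Gaussian convolution of the physical potential,

    K(x) = ∫ dx' U(x') N(x' − x; σ²),   σ² = ℏ²/12mkT,

exact in the free-particle / high-temperature limit.  For a pairwise,
spherically symmetric potential the second-order truncation yields the
pairwise correction

    u_FH(r) = u(r) + (βℏ²/24μ) [u''(r) + 2u'(r)/r],

with μ the reduced mass of the interacting pair.  This module provides
both forms as the cheap baseline against which the learned centroid
correction is compared.
"""

from __future__ import annotations

import numpy as np

from .potentials import PotentialSurface
from .units import HBAR_MECH, mass_of, thermal_beta_mech


class TruncationError(ValueError):
    pass


def reduced_mass(m_i: float, m_j: float) -> float:
    return 1.0 / (1.0 / m_i + 1.0 / m_j)


def fhc_sigma2(m: float, T: float) -> float:
    """Width σ² = ℏ²/12mkT of the Feynman–Hibbs kernel, in Å²."""
    if m <= 0:
        raise ValueError("mass must be positive")
    return thermal_beta_mech(T) * HBAR_MECH**2 / (12.0 * m)


def fhc_pair_correction(
    potential: PotentialSurface,
    species_pair: tuple[str, str],
    r: float | np.ndarray,
    T: float,
    masses: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order Feynman–Hibbs corrected pair potential.

    Returns ``(u_FH, correction)`` where ``u_FH = u + correction`` and
    ``correction = (βℏ²/24μ)[u'' + 2u'/r]``.  Masses default to the
    element table; pass ``masses`` to override (e.g. isotopes).
    """
    elem_i, elem_j = species_pair
    m_i, m_j = masses if masses is not None else (mass_of(elem_i), mass_of(elem_j))
    mu = reduced_mass(m_i, m_j)
    r = np.asarray(r, dtype=float)
    u, du, d2u = potential.pair_derivatives(elem_i, elem_j, r)
    pref = thermal_beta_mech(T) * HBAR_MECH**2 / (24.0 * mu)
    correction = pref * (d2u + 2.0 * du / r)
    return u + correction, correction


def fhc_convolve_1d(
    x_grid: np.ndarray,
    U_values: np.ndarray,
    m: float,
    T: float,
    mass_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Numerically exact Gaussian convolution of a tabulated 1D potential.

    ``U_values`` must be tabulated on the uniform ``x_grid``.  The result
    is returned on the interior sub-grid where less than ``mass_tol`` of
    the Gaussian kernel falls outside the tabulated domain; if no such
    points exist a :class:`TruncationError` is raised.

    Returns ``(x_out, K_out, sigma2)``.
    """
    from scipy.special import erfc

    x_grid = np.asarray(x_grid, dtype=float)
    U_values = np.asarray(U_values, dtype=float)
    if x_grid.ndim != 1 or x_grid.shape != U_values.shape:
        raise ValueError("x_grid and U_values must be matching 1D arrays")
    h = np.diff(x_grid)
    if not np.allclose(h, h[0], rtol=1e-8):
        raise ValueError("x_grid must be uniform")
    h = float(h[0])
    sigma2 = fhc_sigma2(m, T)
    sigma = np.sqrt(sigma2)
    # half-width k·σ such that the mass outside is erfc(k/√2) < mass_tol
    from scipy.special import erfcinv

    k = np.sqrt(2.0) * erfcinv(mass_tol)
    pad = k * sigma
    inside = (x_grid >= x_grid[0] + pad) & (x_grid <= x_grid[-1] - pad)
    if not np.any(inside):
        raise TruncationError(
            f"grid span {x_grid[-1] - x_grid[0]:.3g} Å too narrow for kernel "
            f"σ = {sigma:.3g} Å at the requested mass tolerance"
        )
    x_out = x_grid[inside]
    if sigma < h / 4.0:
        # kernel narrower than the grid can resolve: quadrature would be
        # inaccurate, but the convolution is the identity to high accuracy
        K = U_values[inside].copy()
        return x_out, K, sigma2
    # trapezoid quadrature (spectrally accurate for smooth integrands)
    diff = x_out[:, None] - x_grid[None, :]
    kernel = np.exp(-0.5 * diff**2 / sigma2) / np.sqrt(2.0 * np.pi * sigma2)
    w = np.full(x_grid.size, h)
    w[0] = w[-1] = h / 2.0
    K = kernel @ (U_values * w)
    return x_out, K, sigma2
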