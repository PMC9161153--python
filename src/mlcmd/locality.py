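"""Analytic theory of ring-polymer delocalization and correction decay.

The imaginary-time path of an atom in a locally harmonic potential
decomposes into Matsubara modes ω_n = 2πn/βℏ.  Summing their Gaussian
second moments gives a closed form for the bead-distribution width

    ⟨x²⟩ = (βℏ²/2π²m) [ −1/(2t²) + (π/2t) coth(πt) ],   t = βℏω/2π,

with ω = √(U″/m) the intrinsic (angular) vibrational frequency of the
atom.  The width is rigorously bounded above by both the free-particle /
Feynman–Hibbs value ℏ²β/12m (high-T limit) and the quantum harmonic
oscillator ground-state variance ℏ/2mω (low-T limit).  From the width one
obtains rigorous bounds on the relative quantum correction to a Coulombic
pair force at separation R, which quantify how localized the quantum
centroid force correction is and justify short ML descriptor cutoffs.

Frequencies are accepted in cm⁻¹ (spectroscopy convention) and converted
internally to rad/fs.  Widths are returned in Å².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import HBAR_MECH, KB_MECH as _KB_MECH, thermal_beta_mech, wavenumber_to_angular


def _coth(z: np.ndarray) -> np.ndarray:
    """coth for z > 0, stable against overflow (coth→1 for large z)."""
    z = np.asarray(z, dtype=float)
    # coth(z) = 1 + 2/(e^{2z} - 1)
    return np.where(z < 350.0, 1.0 + 2.0 / np.expm1(2.0 * np.clip(z, None, 350.0)), 1.0)


def dimensionless_t(T: float | np.ndarray, omega_cm: float) -> np.ndarray:
    """t = βℏω/2π for ω given in cm⁻¹."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    omega = wavenumber_to_angular(omega_cm)
    return HBAR_MECH * omega / (2.0 * np.pi * _KB_MECH * T)


def fhc_width(T: float | np.ndarray, m: float) -> np.ndarray:
    """Free-particle (Feynman–Hibbs kernel) width ℏ²β/12m in Å²."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or m <= 0:
        raise ValueError("T and m must be positive")
    return HBAR_MECH**2 / (12.0 * m * _KB_MECH * T)


def qho_width(m: float, omega_cm: float) -> float:
    """Harmonic-oscillator ground-state variance ℏ/2mω in Å²."""
    if m <= 0 or omega_cm <= 0:
        raise ValueError("m and omega must be positive")
    omega = wavenumber_to_angular(omega_cm)
    return HBAR_MECH / (2.0 * m * omega)


def matsubara_width(T: float | np.ndarray, m: float, omega_cm: float) -> np.ndarray:
    """Closed-form bead-distribution second moment ⟨x²⟩ (Å²).

    ``omega_cm = 0`` is handled by its analytic free-particle limit
    ℏ²β/12m.  Scalar in, scalar out; arrays broadcast over temperature.
    """
    scalar = np.ndim(T) == 0
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T <= 0) or m <= 0 or omega_cm < 0:
        raise ValueError("require T > 0, m > 0, omega ≥ 0")
    beta = 1.0 / (_KB_MECH * T)
    pref = beta * HBAR_MECH**2 / (2.0 * np.pi**2 * m)
    if omega_cm == 0.0:
        out = pref * np.pi**2 / 6.0  # = ℏ²β/12m
    else:
        omega = wavenumber_to_angular(omega_cm)
        t = beta * HBAR_MECH * omega / (2.0 * np.pi)
        out = np.empty_like(t)
        small = t < 1e-4
        # series: −1/2t² + (π/2t)coth(πt) = π²/6 − π⁴t²/90 + O(t⁴)
        ts = t[small]
        out[small] = pref[small] * (np.pi**2 / 6.0 - np.pi**4 * ts**2 / 90.0)
        tl = t[~small]
        bracket = -1.0 / (2.0 * tl**2) + (np.pi / (2.0 * tl)) * _coth(np.pi * tl)
        out[~small] = pref[~small] * bracket
    return float(out[0]) if scalar else out


def matsubara_width_sum(
    T: float, m: float, omega_cm: float, n_max: int = 1_000_000
) -> float:
    """Independent direct Matsubara summation of ⟨x²⟩ with tail correction.

    Evaluates (βℏ²/2π²m) Σ_{n=1..n_max} 1/(n²+t²) plus the integral tail
    Σ_{n>n_max} ≈ ∫_{n_max+½}^∞ dn/(n²+t²); serves as the oracle for the
    closed form.
    """
    if T <= 0 or m <= 0 or omega_cm < 0:
        raise ValueError("require T > 0, m > 0, omega ≥ 0")
    beta = thermal_beta_mech(T)
    omega = wavenumber_to_angular(omega_cm)
    t = beta * HBAR_MECH * omega / (2.0 * np.pi)
    n = np.arange(1, n_max + 1, dtype=float)
    s = np.sum(1.0 / (n**2 + t**2))
    edge = n_max + 0.5
    if t == 0.0:
        tail = 1.0 / edge
    else:
        tail = (np.pi / 2.0 - np.arctan(edge / t)) / t
    return beta * HBAR_MECH**2 / (2.0 * np.pi**2 * m) * (s + tail)


def force_correction_bound(
    R: float,
    x2_i: float,
    x2_j: float,
    drop_correlation: bool = True,
) -> float:
    """Relative bound on the quantum correction to a Coulombic pair force.

    With the bead-position cross-correlation dropped the bound is
    (3/R²)(⟨x_i²⟩+⟨x_j²⟩); the Cauchy–Schwarz worst case (correlation
    fully anti-aligned) is 12·max(⟨x²⟩)/R².  Dimensionless (fractional).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if x2_i < 0 or x2_j < 0:
        raise ValueError("second moments must be non-negative")
    if drop_correlation:
        return 3.0 / R**2 * (x2_i + x2_j)
    return 12.0 * max(x2_i, x2_j) / R**2


@dataclass
class WidthProfile:
    """Bead-distribution width vs temperature, with both rigorous bounds."""

    temperature: np.ndarray  # K
    mass: float  # amu
    omega_cm: float  # cm⁻¹
    x2: np.ndarray  # Å²
    fhc_bound: np.ndarray  # Å²
    qho_bound: float  # Å²
    t: np.ndarray  # dimensionless βℏω/2π

    @property
    def rms(self) -> np.ndarray:
        return np.sqrt(self.x2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": self.temperature,
                "t": self.t,
                "x2_A2": self.x2,
                "rms_A": self.rms,
                "fhc_bound_A2": self.fhc_bound,
                "qho_bound_A2": np.full_like(self.x2, self.qho_bound),
            }
        )


def width_profile(T_grid: np.ndarray, m: float, omega_cm: float) -> WidthProfile:
    """Evaluate the closed-form width and both bounds on a temperature grid."""
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("temperature grid is empty")
    beta = 1.0 / (_KB_MECH * T_grid)
    omega = wavenumber_to_angular(omega_cm)
    return WidthProfile(
        temperature=T_grid,
        mass=m,
        omega_cm=omega_cm,
        x2=matsubara_width(T_grid, m, omega_cm),
        fhc_bound=fhc_width(T_grid, m),
        qho_bound=qho_width(m, omega_cm),
        t=beta * HBAR_MECH * omega / (2.0 * np.pi),
    )
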