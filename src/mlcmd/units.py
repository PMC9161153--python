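"""Internal unit system and physical constants.

Every public API in this package works in a single fixed unit system:

========== =========
quantity   unit
========== =========
length     Å
time       fs
mass       amu
energy     kJ/mol
temperature K
========== =========

These units are *almost* mechanically consistent: 1 amu Å²/fs² equals
1e4 kJ/mol (up to the CODATA molar-mass constant).  Formulas that mix
kinetic and potential terms — ring-polymer spring constants, thermostat
noise, the path-integral width formulas — are therefore evaluated in the
"mechanical" energy unit amu Å²/fs², with conversion to kJ/mol happening
only at module boundaries.  The ``_MECH`` constants below are the ones to
use inside such formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# CODATA 2018
AVOGADRO = 6.02214076e23  # 1/mol
AMU_KG = 1.66053906660e-27  # kg
HBAR_JS = 1.054571817e-34  # J s
KB_JK = 1.380649e-23  # J/K
C_CM_PER_FS = 2.99792458e-5  # speed of light, cm/fs

# Boltzmann constant in kJ/mol/K
KB = KB_JK * AVOGADRO / 1000.0  # 0.008314462618 kJ/mol/K

# hbar in kJ/mol * fs
HBAR = HBAR_JS * AVOGADRO / 1000.0 * 1.0e15  # 63.5077993 kJ/mol fs

# 1 kJ/mol expressed in the mechanical unit amu Å²/fs²
# (amu Å²/fs² = AMU_KG * 1e10 J; kJ/mol = 1000/N_A J)
KJMOL_TO_MECH = (1000.0 / AVOGADRO) / (AMU_KG * 1.0e10)  # ≈ 1.0000e-4
MECH_TO_KJMOL = 1.0 / KJMOL_TO_MECH

KB_MECH = KB * KJMOL_TO_MECH  # amu Å²/fs² / K
HBAR_MECH = HBAR * KJMOL_TO_MECH  # amu Å²/fs


def wavenumber_to_angular(omega_cm: float) -> float:
    """Convert a spectroscopic wavenumber (cm⁻¹) to angular frequency (rad/fs)."""
    return 2.0 * np.pi * C_CM_PER_FS * omega_cm


def thermal_beta(temperature: float) -> float:
    """1/(kB T) in (kJ/mol)⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


def thermal_beta_mech(temperature: float) -> float:
    """1/(kB T) in the mechanical unit (amu Å²/fs²)⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_MECH * temperature)


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the package-wide units and derived constants."""

    length: str = "angstrom"
    time: str = "fs"
    mass: str = "amu"
    energy: str = "kJ/mol"
    temperature: str = "K"
    kB: float = field(default=KB)
    hbar: float = field(default=HBAR)

    def kT(self, temperature: float) -> float:
        return self.kB * temperature


UNITS = UnitSystem()

# Default element masses (amu); toy species must be registered explicitly.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}


def register_element(symbol: str, mass: float) -> None:
    """Register a (possibly fictitious) species with an explicit mass."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    ELEMENT_MASSES[symbol] = float(mass)


def mass_of(symbol: str) -> float:
    try:
        return ELEMENT_MASSES[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element {symbol!r}: register it with "
            "mlcmd.units.register_element(symbol, mass)"
        ) from None
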