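"""Molecular configuration container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import mass_of


@dataclass
class MolecularConfiguration:
    """An N-atom configuration: species, positions (Å), masses (amu).

    ``cell`` holds the three orthorhombic box lengths in Å when
    ``periodic`` is true; non-periodic clusters leave it as ``None``.
    Atom ordering is significant and preserved through all I/O.
    """

    elements: list[str]
    positions: np.ndarray  # (N, 3) Å
    masses: np.ndarray | None = None  # (N,) amu
    cell: np.ndarray | None = None  # (3,) Å
    periodic: bool = False

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.elements) != self.positions.shape[0]:
            raise ValueError("elements and positions disagree on atom count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.masses is None:
            self.masses = np.array([mass_of(e) for e in self.elements])
        else:
            self.masses = np.ascontiguousarray(self.masses, dtype=float)
            if self.masses.shape != (self.positions.shape[0],):
                raise ValueError("masses must have shape (N,)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.periodic:
            if self.cell is None:
                raise ValueError("periodic configuration requires a cell")
            self.cell = np.ascontiguousarray(self.cell, dtype=float)
            if self.cell.shape != (3,) or np.any(self.cell <= 0):
                raise ValueError("cell must be three positive box lengths")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "MolecularConfiguration":
        return MolecularConfiguration(
            elements=list(self.elements),
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            periodic=self.periodic,
        )

    def with_positions(self, positions: np.ndarray) -> "MolecularConfiguration":
        out = self.copy()
        out.positions = np.ascontiguousarray(positions, dtype=float)
        if out.positions.shape != self.positions.shape:
            raise ValueError("replacement positions must keep the same shape")
        return out


def minimum_image(dr: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors (last axis 3)."""
    if cell is None:
        return dr
    return dr - cell * np.round(dr / cell)
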