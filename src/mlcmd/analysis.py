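"""Structural and dynamical observables: centroid RDFs, MSD and diffusion.

All structure here is computed on centroid (or classical) coordinates —
the coarse-grained variables that centroid MD propagates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import MDTrajectory
from .geometry import minimum_image


@dataclass
class RDFResult:
    pair: tuple[str, str]
    r: np.ndarray  # bin centers, Å
    g: np.ndarray
    n_frames: int
    density_j: float  # number density of the partner species, 1/Å³
    n_i: int
    metadata: dict = field(default_factory=dict)

    def neighbor_count(self, r_max: float | None = None) -> float:
        """∫ ρ_j g(r) 4πr² dr with the histogram's own binning."""
        edges = self.metadata["edges"]
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        mask = np.ones_like(self.g, dtype=bool)
        if r_max is not None:
            mask = edges[1:] <= r_max
        return float(np.sum(self.g[mask] * shell[mask]) * self.density_j)


def rdf(
    trajectory: MDTrajectory | tuple[np.ndarray, np.ndarray, list[str]],
    species_pair: tuple[str, str],
    r_max: float,
    n_bins: int = 100,
) -> RDFResult:
    """Shell-volume-normalized pair distribution over frames.

    Accepts either an :class:`MDTrajectory` or a raw
    ``(positions (F,N,3), cell (3,), elements)`` triple.
    """
    if isinstance(trajectory, MDTrajectory):
        positions = trajectory.positions
        cfg = trajectory.config
        if not cfg.periodic:
            raise ValueError("rdf requires a periodic trajectory")
        cell, elements = cfg.cell, cfg.elements
    else:
        positions, cell, elements = trajectory
        cell = np.asarray(cell, dtype=float)
    if r_max > min(cell) / 2:
        raise ValueError("r_max exceeds half the shortest box length")
    ei, ej = species_pair
    idx_i = np.array([k for k, e in enumerate(elements) if e == ei])
    idx_j = np.array([k for k, e in enumerate(elements) if e == ej])
    if idx_i.size == 0 or idx_j.size == 0:
        raise ValueError(f"species pair {species_pair} not present")
    V = float(np.prod(cell))
    rho_j = idx_j.size / V
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    F = positions.shape[0]
    same = ei == ej
    for f in range(F):
        pos = positions[f]
        d = pos[idx_i][:, None, :] - pos[idx_j][None, :, :]
        d = minimum_image(d, cell)
        r = np.linalg.norm(d, axis=-1)
        if same:
            iu = ~np.eye(idx_i.size, dtype=bool)
            r = r[iu]
        else:
            r = r.ravel()
        hist += np.histogram(r, bins=edges)[0]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = F * idx_i.size * rho_j * shell
    g = hist / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        pair=species_pair,
        r=centers,
        g=g,
        n_frames=F,
        density_j=rho_j,
        n_i=idx_i.size,
        metadata={"edges": edges, "counts": hist},
    )


def unwrap_positions(positions: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    """Remove periodic jumps by accumulating minimum-image displacements."""
    if cell is None:
        return positions.copy()
    out = np.empty_like(positions)
    out[0] = positions[0]
    for f in range(1, positions.shape[0]):
        step = minimum_image(positions[f] - positions[f - 1], cell)
        out[f] = out[f - 1] + step
    return out


def msd_curve(
    positions_unwrapped: np.ndarray,
    dt_frame: float,
    max_lag_fraction: float = 0.5,
    origin_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-time-origin mean-squared displacement.

    Returns ``(lag times fs, MSD Å²)`` averaged over atoms and origins.
    """
    F = positions_unwrapped.shape[0]
    max_lag = max(2, int(F * max_lag_fraction))
    lags = np.arange(1, max_lag)
    msd = np.empty(lags.size)
    for li, lag in enumerate(lags):
        d = positions_unwrapped[lag:] - positions_unwrapped[:-lag]
        d = d[::origin_stride]
        msd[li] = np.mean(np.sum(d**2, axis=-1))
    return lags * dt_frame, msd


@dataclass
class MSDResult:
    t: np.ndarray  # lag times, fs
    msd: np.ndarray  # Å²
    D: float  # Å²/ps
    exponent: float  # log-log slope over the fit window
    diffusive: bool  # exponent close to 1

    def __iter__(self):  # (t, msd, D) unpacking convenience
        return iter((self.t, self.msd, self.D))


def msd_diffusion(
    trajectory: MDTrajectory,
    species: str | None = None,
    fit_window: tuple[float, float] | None = None,
    dim: int = 3,
) -> MSDResult:
    """Self-diffusion constant from the Einstein relation.

    Fits MSD = 2·dim·D·t over ``fit_window`` (fs); D is reported in
    Å²/ps.  The log-log slope over the window flags non-diffusive
    (ballistic or arrested) regimes.
    """
    cfg = trajectory.config
    if species is None:
        sel = np.arange(cfg.n_atoms)
    else:
        sel = np.array([k for k, e in enumerate(cfg.elements) if e == species])
        if sel.size == 0:
            raise ValueError(f"no atoms of species {species!r}")
    cell = cfg.cell if cfg.periodic else None
    unwrapped = unwrap_positions(trajectory.positions[:, sel, :], cell)
    dt_frame = trajectory.dt * trajectory.stride
    t, msd = msd_curve(unwrapped, dt_frame)
    if fit_window is None:
        fit_window = (t[-1] * 0.2, t[-1] * 0.8)
    lo, hi = fit_window
    if lo >= t[-1] or hi > t[-1] or lo >= hi:
        raise ValueError("fit window outside the available lag range")
    mask = (t >= lo) & (t <= hi)
    slope, _ = np.polyfit(t[mask], msd[mask], 1)
    D = slope / (2.0 * dim) * 1000.0  # Å²/fs → Å²/ps
    pos_mask = mask & (msd > 0)
    if pos_mask.sum() >= 2:
        exponent, _ = np.polyfit(np.log(t[pos_mask]), np.log(msd[pos_mask]), 1)
    else:
        exponent = np.nan
    return MSDResult(
        t=t, msd=msd, D=float(D), exponent=float(exponent),
        diffusive=bool(abs(exponent - 1.0) < 0.3),
    )
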