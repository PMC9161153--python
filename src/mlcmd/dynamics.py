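"""Classical MD and ML-CMD propagation.

ML-CMD is classical molecular dynamics driven by the classical force plus
the learned quantum centroid-force correction: the centroid moves on the
learned approximation to the centroid potential of mean force at the cost
of a classical simulation.  The propagator is the P = 1 special case of
the ring-polymer integrator, so classical MD, ML-CMD and PIMD share one
integration code path and classical MD with ``correction=None`` is
bitwise identical to a zero-bead-spring ring polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MolecularConfiguration, minimum_image
from .potentials import PotentialSurface
from .ringpolymer import PIMDIntegrator
from .units import KB, KB_MECH, MECH_TO_KJMOL

# 1 kJ/mol/Å³ in bar
PRESSURE_BAR = 1.66053906717e4


@dataclass
class MDTrajectory:
    """Frames plus a per-frame thermodynamic log."""

    config: MolecularConfiguration  # topology template
    positions: np.ndarray  # (F, N, 3) Å
    velocities: np.ndarray  # (F, N, 3) Å/fs
    thermo: pd.DataFrame  # step, time_fs, T_inst, E_pot
    ensemble: str
    dt: float
    stride: int
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> MolecularConfiguration:
        return self.config.with_positions(self.positions[i])


def run_md(
    potential: PotentialSurface,
    correction,  # CorrectionModel | None
    config0: MolecularConfiguration,
    ensemble: str = "nvt",
    T: float = 300.0,
    dt: float = 0.5,
    n_steps: int = 1000,
    seed: int = 0,
    friction: float = 1.0e-3,
    stride: int = 10,
    velocities0: np.ndarray | None = None,
) -> MDTrajectory:
    """Velocity-Verlet / Langevin MD, optionally with a learned ΔF_c.

    ``ensemble`` is ``"nvt"`` (Langevin, default friction 1.0 ps⁻¹) or
    ``"nve"``.  The trajectory stores every ``stride``-th frame plus the
    initial one.
    """
    ensemble = ensemble.lower()
    if ensemble not in ("nvt", "nve"):
        raise ValueError(f"unknown ensemble {ensemble!r}")

    extra = None
    if correction is not None:
        def extra(beads: np.ndarray) -> np.ndarray:
            out = np.empty_like(beads)
            for k in range(beads.shape[0]):
                out[k] = correction.predict_delta_forces(
                    config0.with_positions(beads[k])
                )
            return out

    integ = PIMDIntegrator(
        potential,
        config0,
        P=1,
        temperature=T,
        dt=dt,
        friction=friction if ensemble == "nvt" else None,
        rng=seed,
        extra_force=extra,
    )
    integ.initialize(
        momenta=None if velocities0 is None
        else (velocities0 * config0.masses[:, None])[None],
        sample_momenta=velocities0 is None,
    )
    n_frames = n_steps // stride + 1
    N = config0.n_atoms
    pos = np.empty((n_frames, N, 3))
    vel = np.empty((n_frames, N, 3))
    rows = []
    masses = config0.masses[:, None]

    def record(fi: int):
        pos[fi] = integ.bead_positions[0]
        vel[fi] = integ._Pm[0] / masses
        ekin_mech = 0.5 * float(np.sum(masses * vel[fi] ** 2))
        t_inst = 2.0 * ekin_mech / (3 * N * KB_MECH)
        rows.append(
            {
                "step": integ.n_steps_done,
                "time_fs": integ.n_steps_done * dt,
                "T_inst": t_inst,
                "E_pot": integ._energy,
                "E_kin": ekin_mech * MECH_TO_KJMOL,
            }
        )

    record(0)
    for fi in range(1, n_frames):
        integ.step(stride)
        record(fi)
    return MDTrajectory(
        config=config0,
        positions=pos,
        velocities=vel,
        thermo=pd.DataFrame(rows),
        ensemble=ensemble,
        dt=dt,
        stride=stride,
        seed=seed,
        metadata={"T": T, "friction": friction, "corrected": correction is not None},
    )


def pair_virial(potential: PotentialSurface, config: MolecularConfiguration) -> float:
    """W = −Σ_{i<j} r_ij u'(r_ij) (kJ/mol), minimum image, within cutoff."""
    if not potential.pairwise:
        raise ValueError("virial requires a pairwise potential")
    cell = config.cell if config.periodic else None
    cutoff = getattr(potential, "cutoff", None)
    W = 0.0
    pos = config.positions
    N = config.n_atoms
    for i in range(N):
        dr = pos[i + 1 :] - pos[i]
        dr = minimum_image(dr, cell)
        r = np.linalg.norm(dr, axis=1)
        for jj, rv in enumerate(r):
            if cutoff is not None and rv >= cutoff:
                continue
            j = i + 1 + jj
            _, du, _ = potential.pair_derivatives(
                config.elements[i], config.elements[j], rv
            )
            W -= rv * float(du)
    return W


def virial_pressure(
    trajectory: MDTrajectory, potential: PotentialSurface
) -> np.ndarray:
    """Instantaneous pair-virial pressure per frame, in bar.

    P = (N kB T_inst + W/3) / V with W the pair virial; periodic systems
    only.
    """
    cfg = trajectory.config
    if not cfg.periodic:
        raise ValueError("pressure requires a periodic system")
    V = float(np.prod(cfg.cell))
    N = cfg.n_atoms
    out = np.empty(trajectory.n_frames)
    for fi in range(trajectory.n_frames):
        frame = cfg.with_positions(trajectory.positions[fi])
        W = pair_virial(potential, frame)
        t_inst = trajectory.thermo["T_inst"].iloc[fi]
        out[fi] = (N * KB * t_inst + W / 3.0) / V * PRESSURE_BAR
    return out
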