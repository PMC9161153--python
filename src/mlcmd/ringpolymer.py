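"""Ring-polymer representation and thermostatted PIMD sampling.

The quantum partition function of an atom at inverse temperature β is
isomorphic to that of a classical cyclic polymer of P beads connected by
springs of frequency ω_P = √P/βℏ, each bead feeling the physical
potential scaled by 1/P.  This module provides the state container, the
normal-mode machinery that diagonalizes the cyclic spring matrix, a
velocity-Verlet integrator with exact free-ring-polymer evolution and
per-mode Langevin (PILE) friction, and the fixed-centroid sampling mode
that produces quantum centroid-force training labels: with the centroid
mode frozen, the time average of the bead-averaged physical force
converges to the centroid mean force F_c, whose difference from the
classical force at the centroid geometry is the learning target ΔF_c.

Classical MD is the exact P = 1 special case of the same integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MolecularConfiguration
from .potentials import PotentialSurface
from .random import seeded_rng
from .units import (
    HBAR_MECH,
    KB,
    KB_MECH,
    KJMOL_TO_MECH,
    MECH_TO_KJMOL,
    thermal_beta_mech,
)


@dataclass
class RingPolymerState:
    """P replicas of an N-atom configuration with momenta (amu Å/fs)."""

    beads: np.ndarray  # (P, N, 3) Å
    momenta: np.ndarray  # (P, N, 3) amu Å/fs
    masses: np.ndarray  # (N,) amu
    temperature: float  # K

    def __post_init__(self):
        self.beads = np.ascontiguousarray(self.beads, dtype=float)
        self.momenta = np.ascontiguousarray(self.momenta, dtype=float)
        if self.beads.ndim != 3 or self.beads.shape != self.momenta.shape:
            raise ValueError("beads and momenta must both have shape (P, N, 3)")
        if self.beads.shape[0] < 1:
            raise ValueError("need at least one bead")

    @property
    def P(self) -> int:
        return self.beads.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.beads.shape[1]


def centroid(state: RingPolymerState) -> np.ndarray:
    """Per-atom arithmetic mean over beads, (N, 3) Å."""
    return state.beads.mean(axis=0)


def spring_frequency(P: int, temperature: float) -> float:
    """ω_P = √P / βℏ in rad/fs."""
    return np.sqrt(P) / (thermal_beta_mech(temperature) * HBAR_MECH)


def spring_energy(state: RingPolymerState) -> float:
    """Σ_k ½ m ω_P² |x_{k+1} − x_k|², cyclic, in kJ/mol. Zero for P = 1."""
    if state.P == 1:
        return 0.0
    w2 = spring_frequency(state.P, state.temperature) ** 2
    d = state.beads - np.roll(state.beads, -1, axis=0)
    return float(0.5 * w2 * np.sum(state.masses[None, :, None] * d**2) * MECH_TO_KJMOL)


def normal_mode_matrix(P: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal real transform C diagonalizing the cyclic spring matrix.

    Returns ``(C, k_index)``: mode coordinates are ``Q = C @ beads`` (bead
    axis first); row 0 is the centroid scaled by √P, i.e. ``Q[0] =
    √P·centroid``.  ``k_index[j]`` is the integer Fourier index |k| of
    mode j, so the free-ring-polymer frequency of mode j is
    ``2 ω_P sin(π k_index[j] / P)``.
    """
    j = np.arange(P)
    C = np.empty((P, P))
    k_index = np.zeros(P, dtype=int)
    C[0] = 1.0 / np.sqrt(P)
    row = 1
    for k in range(1, P // 2 + 1):
        if 2 * k == P:
            C[row] = (-1.0) ** j / np.sqrt(P)
            k_index[row] = k
            row += 1
        else:
            C[row] = np.sqrt(2.0 / P) * np.cos(2.0 * np.pi * k * j / P)
            k_index[row] = k
            C[row + 1] = np.sqrt(2.0 / P) * np.sin(2.0 * np.pi * k * j / P)
            k_index[row + 1] = k
            row += 2
    return C, k_index


def normal_mode_transform(state: RingPolymerState) -> np.ndarray:
    """Mode coordinates Q = C·beads, shape (P, N, 3)."""
    C, _ = normal_mode_matrix(state.P)
    return np.einsum("pq,qnd->pnd", C, state.beads)


def normal_mode_inverse(modes: np.ndarray) -> np.ndarray:
    C, _ = normal_mode_matrix(modes.shape[0])
    return np.einsum("qp,qnd->pnd", C, modes)


class PIMDIntegrator:
    """OBABO path-integral Langevin integrator in normal-mode coordinates.

    Free-ring-polymer evolution is exact per mode; the physical force
    enters as F/P; PILE friction uses the supplied friction constant on
    the centroid mode and 2ω_k on internal modes.  ``fixed_centroid``
    freezes the centroid mode (position never drifts, momentum zeroed).
    ``friction=None`` integrates NVE (no O step).

    Forces are exchanged with the potential in kJ/mol/Å; internally the
    integrator works in amu, Å, fs.
    """

    def __init__(
        self,
        potential: PotentialSurface,
        config: MolecularConfiguration,
        P: int,
        temperature: float,
        dt: float = 0.5,
        friction: float | None = 1.0e-3,  # 1/fs; default 1.0 ps⁻¹
        fixed_centroid: bool = False,
        rng: int | np.random.Generator = 0,
        extra_force: "callable | None" = None,
    ):
        self.potential = potential
        self.config = config
        self.P = int(P)
        self.T = float(temperature)
        self.dt = float(dt)
        self.fixed_centroid = bool(fixed_centroid)
        self.rng = seeded_rng(rng)
        self.extra_force = extra_force
        self.masses = config.masses.copy()
        self.C, k_index = normal_mode_matrix(self.P)
        wP = spring_frequency(self.P, self.T) if self.P > 1 else 0.0
        self.omega_k = 2.0 * wP * np.sin(np.pi * k_index / self.P)  # (P,)
        # exact free-RP propagator per mode over dt
        w = self.omega_k
        self._cos = np.cos(w * dt)
        self._sin = np.sin(w * dt)
        self._wsafe = np.where(w > 0, w, 1.0)
        # PILE friction per mode over dt/2
        if friction is None:
            self._c1 = None
        else:
            gamma = np.where(k_index == 0, friction, 2.0 * w)
            self._c1 = np.exp(-gamma * dt / 2.0)
            self._c2 = np.sqrt((1.0 - self._c1**2) * KB_MECH * self.T)[:, None, None] \
                * np.sqrt(self.masses)[None, :, None]
        self._c1_col = None if self._c1 is None else self._c1[:, None, None]
        self.n_steps_done = 0
        self._Q = None  # (P, N, 3) mode positions
        self._Pm = None  # (P, N, 3) mode momenta
        self._force_modes = None
        self._energy = None

    # -- state init ------------------------------------------------------
    def initialize(
        self,
        beads: np.ndarray | None = None,
        momenta: np.ndarray | None = None,
        sample_momenta: bool = True,
    ):
        N = self.config.n_atoms
        if beads is None:
            beads = np.broadcast_to(self.config.positions, (self.P, N, 3)).copy()
        beads = np.asarray(beads, dtype=float).reshape(self.P, N, 3)
        self._Q = np.einsum("pq,qnd->pnd", self.C, beads)
        if momenta is None:
            if sample_momenta:
                sigma = np.sqrt(KB_MECH * self.T * self.masses)
                momenta = self.rng.standard_normal((self.P, N, 3)) * sigma[None, :, None]
            else:
                momenta = np.zeros((self.P, N, 3))
        momenta = np.asarray(momenta, dtype=float).reshape(self.P, N, 3)
        self._Pm = np.einsum("pq,qnd->pnd", self.C, momenta)
        if self.fixed_centroid:
            self._Pm[0] = 0.0
        self._update_forces()
        return self

    def _update_forces(self):
        beads = np.einsum("qp,qnd->pnd", self.C, self._Q)
        e, f = self.potential.evaluate_batch(self.config, beads)
        if self.extra_force is not None:
            f = f + self.extra_force(beads)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite forces at step {self.n_steps_done}"
            )
        self._energy = float(np.sum(e)) / self.P  # Σ U(x_k)/P, kJ/mol
        fm = np.einsum("pq,qnd->pnd", self.C, f) * (KJMOL_TO_MECH / self.P)
        if self.fixed_centroid:
            fm[0] = 0.0
        self._force_modes = fm
        self._beads_cache = beads
        self._forces_cache = f  # physical forces, kJ/mol/Å

    # -- one OBABO step --------------------------------------------------
    def step(self, n: int = 1):
        for _ in range(n):
            self._O()
            self._B()
            self._A()
            self._update_forces()
            self._B()
            self._O()
            self.n_steps_done += 1
        return self

    def _O(self):
        if self._c1 is None:
            return
        noise = self.rng.standard_normal(self._Pm.shape)
        self._Pm *= self._c1_col
        self._Pm += self._c2 * noise
        if self.fixed_centroid:
            self._Pm[0] = 0.0

    def _B(self):
        self._Pm += (0.5 * self.dt) * self._force_modes

    def _A(self):
        m = self.masses[None, :, None]
        q, p = self._Q, self._Pm
        c = self._cos[:, None, None]
        s = self._sin[:, None, None]
        w = self._wsafe[:, None, None]
        free = self.omega_k == 0
        qn = np.where(free[:, None, None], q, c * q + (s / (w * m)) * p)
        pn = np.where(free[:, None, None], p, c * p - (m * w * s) * q)
        # centroid (and any zero-frequency mode): linear drift
        qn[free] = q[free] + self.dt * p[free] / m
        if self.fixed_centroid:
            qn[0] = q[0]
            pn[0] = 0.0
        self._Q, self._Pm = qn, pn

    # -- observables -----------------------------------------------------
    @property
    def state(self) -> RingPolymerState:
        beads = np.einsum("qp,qnd->pnd", self.C, self._Q)
        mom = np.einsum("qp,qnd->pnd", self.C, self._Pm)
        return RingPolymerState(beads, mom, self.masses, self.T)

    @property
    def bead_positions(self) -> np.ndarray:
        return self._beads_cache

    @property
    def bead_forces(self) -> np.ndarray:
        """Physical forces on every bead (kJ/mol/Å), at the last force update."""
        return self._forces_cache

    def centroid_positions(self) -> np.ndarray:
        return self._Q[0] / np.sqrt(self.P)

    def hamiltonian(self) -> float:
        """Kinetic + spring + Σ U(x_k)/P in kJ/mol (conserved in NVE)."""
        m = self.masses[None, :, None]
        kin = 0.5 * np.sum(self._Pm**2 / m)
        spring = 0.5 * np.sum(
            m * (self.omega_k**2)[:, None, None] * self._Q**2
        )
        return (kin + spring) * MECH_TO_KJMOL + self._energy


def pimd_step(
    state: RingPolymerState,
    potential: PotentialSurface,
    config: MolecularConfiguration,
    dt: float = 0.5,
    friction: float | None = 1.0e-3,
    fixed_centroid: bool = False,
    rng: int | np.random.Generator = 0,
) -> RingPolymerState:
    """Single-step functional wrapper around :class:`PIMDIntegrator`."""
    integ = PIMDIntegrator(
        potential, config, state.P, state.temperature, dt=dt,
        friction=friction, fixed_centroid=fixed_centroid, rng=rng,
    )
    integ.initialize(beads=state.beads, momenta=state.momenta)
    integ.step()
    return integ.state


# ---------------------------------------------------------------------------
# fixed-centroid labeling


@dataclass
class CentroidForceRecord:
    """One training example: a centroid geometry and its converged mean
    bead force with statistical errors."""

    centroid: MolecularConfiguration
    mean_force: np.ndarray  # (N, 3) kJ/mol/Å
    force_sem: np.ndarray  # (N, 3) kJ/mol/Å
    classical_force: np.ndarray  # (N, 3) kJ/mol/Å
    temperature: float
    P: int
    n_steps: int
    seed: int
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def delta_force(self) -> np.ndarray:
        """ΔF_c = F_c − F_classical, the learning target."""
        return self.mean_force - self.classical_force


def default_bead_count(temperature: float) -> int:
    """Bead-count policy: 32 beads at ≥300 K doubling towards low T (64 at 100 K)."""
    if temperature >= 300.0:
        return 32
    return 64


def sample_fixed_centroid(
    centroid_geom: MolecularConfiguration,
    potential: PotentialSurface,
    T: float,
    P: int | None = None,
    n_steps: int = 100_000,
    seed: int = 0,
    dt: float = 0.5,
    friction: float = 1.0e-3,
    burn_in_fraction: float = 0.1,
    n_blocks: int = 20,
    tolerance: float = 0.2,
) -> CentroidForceRecord:
    """Fixed-centroid PIMD estimate of the quantum centroid force.

    Beads start collapsed on the centroid geometry; after a burn-in
    (default 10% of ``n_steps``) the bead-averaged physical force is
    accumulated every step and its standard error estimated by block
    averaging over ``n_blocks`` blocks.  A record whose maximum SEM
    exceeds ``tolerance`` (kJ/mol/Å) is flagged, not discarded.
    """
    if P is None:
        P = default_bead_count(T)
    burn = int(burn_in_fraction * n_steps)
    n_prod = n_steps - burn
    if n_prod < n_blocks * 2:
        raise ValueError("too few production steps for block averaging")
    integ = PIMDIntegrator(
        potential, centroid_geom, P, T, dt=dt, friction=friction,
        fixed_centroid=True, rng=seed,
    )
    integ.initialize()
    integ.step(burn)
    N = centroid_geom.n_atoms
    block_len = n_prod // n_blocks
    block_means = np.zeros((n_blocks, N, 3))
    for b in range(n_blocks):
        acc = np.zeros((N, 3))
        for _ in range(block_len):
            integ.step()
            acc += integ.bead_forces.mean(axis=0)
        block_means[b] = acc / block_len
    mean_force = block_means.mean(axis=0)
    force_sem = block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    _, classical = potential.evaluate(centroid_geom)
    converged = bool(np.max(force_sem) <= tolerance)
    drift = np.max(np.abs(integ.centroid_positions() - centroid_geom.positions))
    return CentroidForceRecord(
        centroid=centroid_geom,
        mean_force=mean_force,
        force_sem=force_sem,
        classical_force=classical,
        temperature=T,
        P=P,
        n_steps=n_steps,
        seed=seed,
        converged=converged,
        metadata={"centroid_drift": float(drift), "dt": dt, "friction": friction},
    )


def bead_width(
    states: "list[RingPolymerState]",
    atoms: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Time-and-bead average of (x_k − x_c)² per atom and Cartesian dof.

    Returns an (n_atoms_selected, 3) array in Å².
    """
    if len(states) == 0:
        raise ValueError("empty trajectory")
    if atoms is None:
        atoms = np.arange(states[0].n_atoms)
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size == 0:
        raise ValueError("empty atom selection")
    acc = np.zeros((atoms.size, 3))
    for st in states:
        xc = centroid(st)
        d = st.beads[:, atoms, :] - xc[None, atoms, :]
        acc += (d**2).mean(axis=0)
    return acc / len(states)


RECORD_SCHEMA_VERSION = 1


def save_records(path, records: "list[CentroidForceRecord]") -> None:
    """Serialize centroid-force records to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = RECORD_SCHEMA_VERSION
        for i, rec in enumerate(records):
            g = f.create_group(f"record_{i:05d}")
            g.create_dataset("positions", data=rec.centroid.positions)
            g.create_dataset("masses", data=rec.centroid.masses)
            g.attrs["elements"] = ",".join(rec.centroid.elements)
            g.create_dataset("mean_force", data=rec.mean_force)
            g.create_dataset("force_sem", data=rec.force_sem)
            g.create_dataset("classical_force", data=rec.classical_force)
            for k in ("temperature", "P", "n_steps", "seed", "converged"):
                g.attrs[k] = getattr(rec, k)


def load_records(path) -> "list[CentroidForceRecord]":
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != RECORD_SCHEMA_VERSION:
            raise ValueError("unknown record schema version")
        for key in sorted(f.keys()):
            g = f[key]
            cfg = MolecularConfiguration(
                elements=g.attrs["elements"].split(","),
                positions=g["positions"][()],
                masses=g["masses"][()],
            )
            records.append(
                CentroidForceRecord(
                    centroid=cfg,
                    mean_force=g["mean_force"][()],
                    force_sem=g["force_sem"][()],
                    classical_force=g["classical_force"][()],
                    temperature=float(g.attrs["temperature"]),
                    P=int(g.attrs["P"]),
                    n_steps=int(g.attrs["n_steps"]),
                    seed=int(g.attrs["seed"]),
                    converged=bool(g.attrs["converged"]),
                )
            )
    return records


def virial_kinetic_energy(
    integ_samples: "list[tuple[np.ndarray, np.ndarray]]",
    temperature: float,
) -> np.ndarray:
    """Centroid-virial quantum kinetic energy per atom and dof (kJ/mol).

    Each sample is ``(bead_positions (P,N,3), bead_forces (P,N,3))``; the
    estimator is kT/2 − (1/2P)Σ_k ⟨(x_k − x_c)·F(x_k)⟩ per dof.
    """
    if not integ_samples:
        raise ValueError("no samples")
    acc = None
    for beads, forces in integ_samples:
        xc = beads.mean(axis=0)
        v = -0.5 * ((beads - xc[None]) * forces).mean(axis=0)  # (N,3) kJ/mol
        acc = v if acc is None else acc + v
    acc /= len(integ_samples)
    return 0.5 * KB * temperature + acc
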