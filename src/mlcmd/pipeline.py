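"""End-to-end orchestration at toy scale.

The workflow mirrors the cluster-training strategy for bulk molecular
systems: equilibrate a small bulk box, randomly extract compact clusters
(one central molecule plus its first solvation shell), converge the
quantum centroid force on each cluster with fixed-centroid PIMD, train
the localized correction model on the resulting ΔF_c labels, and run
ML-CMD on the bulk system with the trained correction.  Everything is
generated deterministically from seeds — no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularConfiguration, minimum_image
from .potentials import PotentialSurface, ToyWater3
from .random import seeded_rng, spawn_rngs
from .ringpolymer import CentroidForceRecord, sample_fixed_centroid


@dataclass
class ClusterSpec:
    """How to carve clusters out of a bulk molecular trajectory."""

    n_neighbors: int = 7  # cluster = 1 central + n_neighbors molecules
    atoms_per_molecule: int = 3

    @property
    def n_molecules(self) -> int:
        return self.n_neighbors + 1


def molecule_centers(
    config: MolecularConfiguration, atoms_per_molecule: int
) -> np.ndarray:
    """Center of mass of each molecule (first-atom image convention)."""
    N = config.n_atoms
    if N % atoms_per_molecule != 0:
        raise ValueError("atom count not divisible by atoms_per_molecule")
    nmol = N // atoms_per_molecule
    cell = config.cell if config.periodic else None
    centers = np.empty((nmol, 3))
    for m in range(nmol):
        sl = slice(m * atoms_per_molecule, (m + 1) * atoms_per_molecule)
        pos = config.positions[sl]
        ref = pos[0]
        rel = minimum_image(pos - ref, cell)
        w = config.masses[sl][:, None]
        centers[m] = ref + np.sum(w * rel, axis=0) / np.sum(w)
    return centers


def extract_cluster(
    config: MolecularConfiguration,
    center_mol: int,
    spec: ClusterSpec,
) -> MolecularConfiguration:
    """The central molecule plus its ``spec.n_neighbors`` nearest molecules,
    unwrapped to one contiguous image and stripped of periodicity."""
    apm = spec.atoms_per_molecule
    centers = molecule_centers(config, apm)
    nmol = centers.shape[0]
    if nmol < spec.n_molecules:
        raise ValueError(
            f"need ≥{spec.n_molecules} molecules, trajectory has {nmol}"
        )
    cell = config.cell if config.periodic else None
    d = minimum_image(centers - centers[center_mol], cell)
    dist = np.linalg.norm(d, axis=1)
    order = np.argsort(dist)
    chosen = order[: spec.n_molecules]  # center first (distance 0)
    elements: list[str] = []
    positions = []
    masses = []
    ref = centers[center_mol]
    for m in chosen:
        sl = slice(m * apm, (m + 1) * apm)
        elements += config.elements[sl]
        # place the molecule at the image closest to the central molecule,
        # keeping it internally contiguous
        mol_ref = config.positions[sl][0]
        internal = minimum_image(config.positions[sl] - mol_ref, cell)
        shift = ref + minimum_image(mol_ref - ref, cell)
        positions.append(shift + internal)
        masses.append(config.masses[sl])
    return MolecularConfiguration(
        elements=elements,
        positions=np.vstack(positions),
        masses=np.concatenate(masses),
    )


def extract_clusters(
    frames: list[MolecularConfiguration],
    spec: ClusterSpec,
    n_clusters: int,
    seed: int = 0,
) -> list[MolecularConfiguration]:
    """Randomly draw (frame, central molecule) pairs and carve clusters."""
    rng = seeded_rng(seed)
    if not frames:
        raise ValueError("no frames")
    nmol = frames[0].n_atoms // spec.atoms_per_molecule
    out = []
    for _ in range(n_clusters):
        f = int(rng.integers(len(frames)))
        m = int(rng.integers(nmol))
        out.append(extract_cluster(frames[f], m, spec))
    return out


def build_training_set(
    clusters: list[MolecularConfiguration],
    potential: PotentialSurface,
    T: float,
    P: int | None = None,
    n_steps: int = 20_000,
    tolerance: float = 0.2,
    seed: int = 0,
) -> list[CentroidForceRecord]:
    """One fixed-centroid PIMD record per cluster; convergence per record
    is flagged against ``tolerance`` (kJ/mol/Å), not enforced."""
    rngs = spawn_rngs(seed, len(clusters))
    records = []
    for i, cluster in enumerate(clusters):
        rec_seed = int(rngs[i].integers(2**31 - 1))
        rec = sample_fixed_centroid(
            cluster, potential, T, P=P, n_steps=n_steps, seed=rec_seed,
            tolerance=tolerance,
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# fixture generation


def make_toywater_box(
    n_molecules: int = 30,
    density_gml: float = 0.997,
    seed: int = 0,
    relax_steps: int = 200,
    potential: ToyWater3 | None = None,
) -> MolecularConfiguration:
    """A periodic toy-water box at the requested mass density.

    Molecules are inserted with rejection sampling (O–O ≥ 2.4 Å) and the
    configuration is relaxed by damped steepest descent to remove the
    worst contacts.  Deterministic per seed.
    """
    rng = seeded_rng(seed)
    m_mol = 15.999 + 2 * 1.008
    # V [Å³] = n·m[amu]·1.66054e-24 g / ρ / 1e-24 cm³/Å³
    V = n_molecules * m_mol * 1.66053906660 / density_gml
    box = V ** (1.0 / 3.0)
    cell = np.array([box, box, box])
    pot = potential or ToyWater3(cutoff=min(4.5, box / 2 * 0.99))

    centers = []
    for _ in range(200000):
        if len(centers) == n_molecules:
            break
        trial = rng.uniform(0, box, 3)
        ok = True
        for c in centers:
            d = minimum_image(trial - c, cell)
            if np.linalg.norm(d) < 2.4:
                ok = False
                break
        if ok:
            centers.append(trial)
    if len(centers) < n_molecules:
        raise RuntimeError("could not insert all molecules at this density")

    r0 = 1.0
    theta0 = 1.910611932
    elements, positions = [], []
    for c in centers:
        # random orientation
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= u * (u @ v)
        v /= np.linalg.norm(v)
        h1 = c + r0 * u
        h2 = c + r0 * (np.cos(theta0) * u + np.sin(theta0) * v)
        elements += ["O", "H", "H"]
        positions += [c, h1, h2]
    cfg = MolecularConfiguration(
        elements=elements, positions=np.array(positions), cell=cell, periodic=True
    )
    # damped steepest-descent relaxation
    step = 1e-4
    for _ in range(relax_steps):
        _, f = pot.evaluate(cfg)
        fmax = np.abs(f).max()
        if fmax < 50.0:
            break
        cfg.positions += np.clip(step * f, -0.05, 0.05)
    cfg.positions %= cell
    return cfg


def equilibrate_box(
    cfg: MolecularConfiguration,
    potential: PotentialSurface,
    T: float = 300.0,
    n_steps: int = 2000,
    seed: int = 1,
    dt: float = 0.5,
):
    """Short classical Langevin equilibration; returns an MDTrajectory."""
    from .dynamics import run_md

    return run_md(
        potential, None, cfg, ensemble="nvt", T=T, dt=dt,
        n_steps=n_steps, seed=seed, friction=1e-2, stride=max(n_steps // 50, 1),
    )


_FIXTURES = {}


def fixture(name):
    def deco(fn):
        _FIXTURES[name] = fn
        return fn
    return deco


@fixture("toywater_box_30")
def _fx_box(seed: int):
    return make_toywater_box(30, seed=seed)


@fixture("octamers_50")
def _fx_octamers(seed: int):
    pot = ToyWater3(cutoff=4.5)
    box = make_toywater_box(30, seed=seed)
    traj = equilibrate_box(box, ToyWater3(cutoff=min(4.5, box.cell[0] / 2 * 0.99)), seed=seed + 1)
    frames = [traj.frame(i) for i in range(traj.n_frames // 2, traj.n_frames)]
    return extract_clusters(frames, ClusterSpec(), 50, seed=seed + 2)


@fixture("quartic_scan")
def _fx_quartic(seed: int):
    rng = seeded_rng(seed)
    xs = np.linspace(-1.0, 1.0, 41)
    return [
        MolecularConfiguration(["H"], np.array([[x, 0.0, 0.0]]))
        for x in xs
    ]


def make_fixtures(name: str, seed: int = 0):
    """Deterministically generate a named toy dataset."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[name](seed)
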