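"""Model potential-energy surfaces.

Every surface implements the same contract: ``evaluate(config)`` returns
``(energy kJ/mol, forces N×3 kJ/mol/Å)`` with forces the exact negative
gradient of the energy.  ``evaluate_batch`` evaluates many geometries of
the same topology at once (the hot path of the ring-polymer sampler).

Built-in kinds:

* one-dimensional toys (``Harmonic1D``, ``Quartic1D``, ``Morse1D``) —
  represented as a single atom whose x coordinate is the active degree of
  freedom, so every sampler code path applies unchanged;
* ``LJCoulombCluster`` — pairwise Lennard-Jones plus bare point-charge
  Coulomb for non-periodic clusters, with optional pair exclusions;
* ``ToyWater3`` — a flexible 3-site water-like molecule: harmonic bonds
  and angle inside each molecule, LJ on the heavy site and point charges
  between molecules; optionally periodic under the minimum image with a
  shifted cutoff;
* ``PeriodicPairFluid`` — any pairwise kind under minimum image with a
  shifted-potential cutoff.

Coulomb interactions are bare 1/r (no Ewald); periodic systems are
restricted to short-ranged shifted pair interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularConfiguration
from .units import MECH_TO_KJMOL, register_element

# e²/(4π ε0) in kJ Å / mol / e²
COULOMB_K = 1389.35457644382


class PotentialError(ValueError):
    pass


class PotentialSurface:
    """Energy/force contract for a model system."""

    name: str = "potential"
    pairwise: bool = False

    def evaluate(self, config: MolecularConfiguration) -> tuple[float, np.ndarray]:
        e, f = self.evaluate_batch(config, config.positions[None])
        return float(e[0]), f[0]

    def evaluate_batch(
        self, config: MolecularConfiguration, positions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Energies (B,) and forces (B, N, 3) for a batch of geometries."""
        raise NotImplementedError

    def pair_derivatives(
        self, elem_i: str, elem_j: str, r: float | np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, u', u'') of the bare pair interaction at separation r (Å)."""
        raise PotentialError(f"{self.name} is not a pairwise potential")


# ---------------------------------------------------------------------------
# 1D toys


class OneDimensionalPotential(PotentialSurface):
    """A single active coordinate: the x component of atom ``atom``.

    Subclasses provide vectorized ``u1d`` / ``du1d`` on that coordinate.
    """

    atom: int = 0

    def u1d(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def du1d(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def evaluate_batch(self, config, positions):
        positions = np.asarray(positions, dtype=float)
        x = positions[..., self.atom, 0]
        e = self.u1d(x)
        f = np.zeros_like(positions)
        f[..., self.atom, 0] = -self.du1d(x)
        return np.atleast_1d(e), f


@dataclass
class Harmonic1D(OneDimensionalPotential):
    """U = ½ k x²  (k in kJ/mol/Å²)."""

    k: float = 2.0
    name: str = "harmonic1d"

    @classmethod
    def from_frequency(cls, mass: float, omega: float) -> "Harmonic1D":
        """Build from mass (amu) and angular frequency ω (rad/fs): k = mω²."""
        return cls(k=mass * omega**2 * MECH_TO_KJMOL)

    def u1d(self, x):
        return 0.5 * self.k * np.asarray(x) ** 2

    def du1d(self, x):
        return self.k * np.asarray(x)


@dataclass
class Quartic1D(OneDimensionalPotential):
    """U = ¼ c x⁴  (c in kJ/mol/Å⁴)."""

    c: float = 10.0
    name: str = "quartic1d"

    def u1d(self, x):
        return 0.25 * self.c * np.asarray(x) ** 4

    def du1d(self, x):
        return self.c * np.asarray(x) ** 3


@dataclass
class Morse1D(OneDimensionalPotential):
    """U = D (1 − e^{−a x})²  (D kJ/mol, a 1/Å)."""

    D: float = 400.0
    a: float = 2.0
    name: str = "morse1d"

    def u1d(self, x):
        g = 1.0 - np.exp(-self.a * np.asarray(x))
        return self.D * g**2

    def du1d(self, x):
        ex = np.exp(-self.a * np.asarray(x))
        return 2.0 * self.D * (1.0 - ex) * self.a * ex


class AnchoredOscillators(PotentialSurface):
    """An ensemble of independent 1D systems sharing one configuration.

    Atoms alternate (active, anchor): each active atom feels the base 1D
    potential along the x displacement from its own anchor plus a stiff
    transverse harmonic tether (k_t) in y and z.  Anchors take the exact
    reaction force, so the potential is translation invariant.  Placing
    the anchors ≥ twice any descriptor cutoff apart makes the walkers
    statistically independent replicas of the same anchored pair — a way
    to batch 1D statistics through the ordinary many-atom machinery.
    """

    name = "anchored_oscillators"

    def __init__(self, base: "OneDimensionalPotential", k_transverse: float = 1000.0):
        self.base = base
        self.k_t = float(k_transverse)

    def evaluate_batch(self, config, positions):
        positions = np.asarray(positions, dtype=float)
        B, N, _ = positions.shape
        if N % 2 != 0:
            raise PotentialError("anchored_oscillators expects (active, anchor) pairs")
        d = positions[:, 0::2, :] - positions[:, 1::2, :]  # (B, W, 3)
        dx = d[..., 0]
        e = self.base.u1d(dx).sum(axis=-1) + 0.5 * self.k_t * np.sum(
            d[..., 1:] ** 2, axis=(-1, -2)
        )
        f_active = np.empty_like(d)
        f_active[..., 0] = -self.base.du1d(dx)
        f_active[..., 1:] = -self.k_t * d[..., 1:]
        forces = np.zeros_like(positions)
        forces[:, 0::2, :] = f_active
        forces[:, 1::2, :] = -f_active
        return np.atleast_1d(e), forces


# ---------------------------------------------------------------------------
# pair interaction primitives


@dataclass(frozen=True)
class LJPair:
    epsilon: float  # kJ/mol
    sigma: float  # Å

    def u(self, r):
        s6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (s6**2 - s6)

    def du(self, r):
        s6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (-12.0 * s6**2 + 6.0 * s6) / r

    def d2u(self, r):
        s6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (156.0 * s6**2 - 42.0 * s6) / r**2


@dataclass(frozen=True)
class CoulombPair:
    qq: float  # product of charges, e²

    def u(self, r):
        return COULOMB_K * self.qq / r

    def du(self, r):
        return -COULOMB_K * self.qq / r**2

    def d2u(self, r):
        return 2.0 * COULOMB_K * self.qq / r**3


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# LJ + Coulomb cluster


class LJCoulombCluster(PotentialSurface):
    """Σ_{i<j} 4ε[(σ/r)¹²−(σ/r)⁶] + k q_i q_j / r for a non-periodic cluster.

    ``lj`` maps species pairs to (ε, σ); pairs absent from the table have no
    LJ term.  ``charges`` maps species to charges in e.  ``exclusions`` is a
    set of atom-index pairs with no interaction at all (used for
    intramolecular terms handled elsewhere).
    """

    pairwise = True
    name = "lj_coulomb_cluster"

    def __init__(
        self,
        lj: dict[tuple[str, str], tuple[float, float]] | None = None,
        charges: dict[str, float] | None = None,
        exclusions: set[tuple[int, int]] | None = None,
    ):
        self.lj = { _pair_key(*k): LJPair(*v) for k, v in (lj or {}).items() }
        self.charges = dict(charges or {})
        self.exclusions = {tuple(sorted(p)) for p in (exclusions or set())}

    def _charge(self, elem: str) -> float:
        return self.charges.get(elem, 0.0)

    def pair_derivatives(self, elem_i, elem_j, r):
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise PotentialError("pair separation must be positive")
        u = np.zeros_like(r)
        du = np.zeros_like(r)
        d2u = np.zeros_like(r)
        pair = self.lj.get(_pair_key(elem_i, elem_j))
        if pair is not None:
            u, du, d2u = u + pair.u(r), du + pair.du(r), d2u + pair.d2u(r)
        qq = self._charge(elem_i) * self._charge(elem_j)
        if qq != 0.0:
            cp = CoulombPair(qq)
            u, du, d2u = u + cp.u(r), du + cp.du(r), d2u + cp.d2u(r)
        return u, du, d2u

    def _tables(self, elements: list[str]):
        key = (tuple(elements), frozenset(self.exclusions))
        if getattr(self, "_table_key", None) == key:
            return self._table_cache
        N = len(elements)
        eps = np.zeros((N, N))
        sig = np.ones((N, N))
        for i in range(N):
            for j in range(N):
                p = self.lj.get(_pair_key(elements[i], elements[j]))
                if p is not None:
                    eps[i, j], sig[i, j] = p.epsilon, p.sigma
        q = np.array([self._charge(e) for e in elements])
        qq = COULOMB_K * np.outer(q, q)
        active = ~np.eye(N, dtype=bool)
        for (i, j) in self.exclusions:
            active[i, j] = active[j, i] = False
        eps[~active] = 0.0
        qq[~active] = 0.0
        self._table_key = key
        self._table_cache = (eps, sig, qq, active)
        return self._table_cache

    def evaluate_batch(self, config, positions):
        positions = np.asarray(positions, dtype=float)
        B, N, _ = positions.shape
        eps, sig, qq, active = self._tables(config.elements)
        dr = positions[:, :, None, :] - positions[:, None, :, :]  # (B,N,N,3)
        r2 = np.sum(dr**2, axis=-1)
        if np.any(r2[:, active] < 1e-20):
            raise PotentialError("interacting atoms coincide")
        r2 = np.where(active[None], r2, 1.0)  # dummy on inactive pairs
        inv_r2 = 1.0 / r2
        s6 = (sig[None] ** 2 * inv_r2) ** 3
        u_lj = 4.0 * eps[None] * (s6**2 - s6)
        du_lj_over_r = 4.0 * eps[None] * (-12.0 * s6**2 + 6.0 * s6) * inv_r2
        inv_r = np.sqrt(inv_r2)
        u_c = qq[None] * inv_r
        du_c_over_r = -qq[None] * inv_r * inv_r2
        u = np.where(active[None], u_lj + u_c, 0.0)
        du_over_r = np.where(active[None], du_lj_over_r + du_c_over_r, 0.0)
        energy = 0.5 * u.sum(axis=(1, 2))
        forces = -np.sum(du_over_r[..., None] * dr, axis=2)
        return energy, forces


# ---------------------------------------------------------------------------
# flexible 3-site toy water


#: Default toy-water parameters (SPC/Fw-flavoured but deliberately generic).
TOYWATER_DEFAULTS = {
    "k_bond": 4000.0,  # kJ/mol/Å²
    "r0": 1.0,  # Å
    "k_angle": 300.0,  # kJ/mol/rad²
    "theta0": 1.910611932,  # rad (109.47°)
    "epsilon_OO": 0.65,  # kJ/mol
    "sigma_OO": 3.166,  # Å
    "q_O": -0.82,
    "q_H": 0.41,
}


class ToyWater3(PotentialSurface):
    """Flexible 3-site toy water: molecules are consecutive (O, H, H) triplets.

    Intramolecular: two harmonic O–H bonds and one harmonic H–O–H angle.
    Intermolecular: LJ between O sites plus bare Coulomb between all sites
    of different molecules.  Periodic boxes apply the minimum image with a
    shifted cutoff on the intermolecular terms.
    """

    name = "toywater3"

    def __init__(self, params: dict | None = None, cutoff: float | None = None):
        p = dict(TOYWATER_DEFAULTS)
        p.update(params or {})
        self.params = p
        self.cutoff = cutoff
        self.lj = LJPair(p["epsilon_OO"], p["sigma_OO"])

    def _charges(self, elements: list[str]) -> np.ndarray:
        q = {"O": self.params["q_O"], "H": self.params["q_H"]}
        return np.array([q[e] for e in elements])

    def _check(self, config):
        if config.n_atoms % 3 != 0:
            raise PotentialError("toywater3 expects atoms in (O,H,H) triplets")
        for m in range(config.n_atoms // 3):
            if config.elements[3 * m : 3 * m + 3] != ["O", "H", "H"]:
                raise PotentialError(f"molecule {m} is not an (O,H,H) triplet")
        if config.periodic:
            if self.cutoff is None:
                raise PotentialError("periodic toywater3 requires a cutoff")
            if self.cutoff > min(config.cell) / 2:
                raise PotentialError("cutoff exceeds half the shortest box length")

    def evaluate_batch(self, config, positions):
        self._check(config)
        positions = np.asarray(positions, dtype=float)
        B, N, _ = positions.shape
        nmol = N // 3
        p = self.params
        cell = config.cell if config.periodic else None
        energy = np.zeros(B)
        forces = np.zeros_like(positions)

        # intramolecular bonds and angle (vectorized over molecules)
        o = positions[:, 0::3]  # (B, M, 3)
        h1 = positions[:, 1::3]
        h2 = positions[:, 2::3]
        for h in (h1, h2):
            d = h - o
            if cell is not None:
                d = d - cell * np.round(d / cell)
            r = np.linalg.norm(d, axis=-1)
            energy += 0.5 * p["k_bond"] * np.sum((r - p["r0"]) ** 2, axis=-1)
            fh = (-p["k_bond"] * (r - p["r0"]) / r)[..., None] * d
            idx = 1 if h is h1 else 2
            forces[:, idx::3] += fh
            forces[:, 0::3] -= fh
        # angle H1-O-H2
        a = h1 - o
        b = h2 - o
        if cell is not None:
            a = a - cell * np.round(a / cell)
            b = b - cell * np.round(b / cell)
        ra = np.linalg.norm(a, axis=-1)
        rb = np.linalg.norm(b, axis=-1)
        cos_t = np.sum(a * b, axis=-1) / (ra * rb)
        cos_t = np.clip(cos_t, -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cos_t)
        energy += 0.5 * p["k_angle"] * np.sum((theta - p["theta0"]) ** 2, axis=-1)
        dE_dtheta = p["k_angle"] * (theta - p["theta0"])  # (B, M)
        sin_t = np.sqrt(1.0 - cos_t**2)
        # dθ/da = (cosθ·â − b̂)/(ra sinθ), dθ/db symmetric
        ahat = a / ra[..., None]
        bhat = b / rb[..., None]
        dth_da = (cos_t[..., None] * ahat - bhat) / (ra * sin_t)[..., None]
        dth_db = (cos_t[..., None] * bhat - ahat) / (rb * sin_t)[..., None]
        fa = -dE_dtheta[..., None] * dth_da
        fb = -dE_dtheta[..., None] * dth_db
        forces[:, 1::3] += fa
        forces[:, 2::3] += fb
        forces[:, 0::3] -= fa + fb

        # intermolecular: LJ(O-O) + Coulomb(all pairs of different molecules)
        key = tuple(config.elements)
        if getattr(self, "_table_key", None) != key:
            q = self._charges(config.elements)
            qq = COULOMB_K * np.outer(q, q)
            mol = np.arange(N) // 3
            active = mol[:, None] != mol[None, :]
            is_o = np.array([e == "O" for e in config.elements])
            ljmask = np.logical_and.outer(is_o, is_o) & active
            qq[~active] = 0.0
            ushift = np.zeros((N, N))
            if self.cutoff is not None:
                ushift = qq / self.cutoff + np.where(
                    ljmask, self.lj.u(self.cutoff), 0.0
                )
            self._table_key = key
            self._tables = (qq, active, ljmask, ushift)
        qq, active, ljmask, ushift = self._tables
        dr = positions[:, :, None, :] - positions[:, None, :, :]
        if cell is not None:
            dr = dr - cell * np.round(dr / cell)
        r2 = np.sum(dr**2, axis=-1)
        if np.any(r2[:, active] < 1e-20):
            raise PotentialError("intermolecular atoms coincide")
        r2 = np.where(active[None], r2, 1.0)
        inv_r2 = 1.0 / r2
        inv_r = np.sqrt(inv_r2)
        u = qq[None] * inv_r
        du_over_r = -qq[None] * inv_r * inv_r2
        s6 = np.where(ljmask[None], (self.lj.sigma**2 * inv_r2) ** 3, 0.0)
        u = u + 4.0 * self.lj.epsilon * (s6**2 - s6)
        du_over_r = du_over_r + 4.0 * self.lj.epsilon * (-12.0 * s6**2 + 6.0 * s6) * inv_r2
        if self.cutoff is not None:
            inside = (r2 < self.cutoff**2) & active[None]
        else:
            inside = np.broadcast_to(active[None], r2.shape)
        u = np.where(inside, u - ushift[None], 0.0)
        du_over_r = np.where(inside, du_over_r, 0.0)
        energy += 0.5 * u.sum(axis=(1, 2))
        forces += -np.sum(du_over_r[..., None] * dr, axis=2)
        return energy, forces


# ---------------------------------------------------------------------------
# periodic pair fluid


class PeriodicPairFluid(PotentialSurface):
    """A pairwise species-tabulated potential under minimum image with a
    shifted cutoff: u_eff(r) = u(r) − u(r_c) for r < r_c, else 0."""

    pairwise = True
    name = "periodic_pair_fluid"

    def __init__(self, pairs: dict[tuple[str, str], LJPair | CoulombPair], cutoff: float):
        if cutoff <= 0:
            raise PotentialError("cutoff must be positive")
        self.pairs = { _pair_key(*k): v for k, v in pairs.items() }
        self.cutoff = cutoff

    def pair_derivatives(self, elem_i, elem_j, r):
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise PotentialError("pair separation must be positive")
        pair = self.pairs.get(_pair_key(elem_i, elem_j))
        if pair is None:
            raise PotentialError(f"no parameters for pair ({elem_i}, {elem_j})")
        return pair.u(r), pair.du(r), pair.d2u(r)

    def evaluate_batch(self, config, positions):
        if not config.periodic:
            raise PotentialError("periodic_pair_fluid requires a periodic configuration")
        if self.cutoff > min(config.cell) / 2:
            raise PotentialError("cutoff exceeds half the shortest box length")
        positions = np.asarray(positions, dtype=float)
        B, N, _ = positions.shape
        cell = config.cell
        energy = np.zeros(B)
        forces = np.zeros_like(positions)
        for i in range(N):
            for j in range(i + 1, N):
                pair = self.pairs.get(_pair_key(config.elements[i], config.elements[j]))
                if pair is None:
                    raise PotentialError(
                        f"no parameters for pair ({config.elements[i]}, {config.elements[j]})"
                    )
                dr = positions[:, i] - positions[:, j]
                dr = dr - cell * np.round(dr / cell)
                r = np.linalg.norm(dr, axis=1)
                inside = r < self.cutoff
                rsafe = np.where(inside, r, self.cutoff)
                u = np.where(inside, pair.u(rsafe) - pair.u(self.cutoff), 0.0)
                du = np.where(inside, pair.du(rsafe), 0.0)
                energy += u
                fij = np.where(inside, -du / r, 0.0)[:, None] * dr
                forces[:, i] += fij
                forces[:, j] -= fij
        return energy, forces


# ---------------------------------------------------------------------------


def numeric_forces(
    potential: PotentialSurface, config: MolecularConfiguration, h: float = 1e-5
) -> np.ndarray:
    """Central-finite-difference forces, the generic gradient oracle."""
    f = np.zeros_like(config.positions)
    for i in range(config.n_atoms):
        for k in range(3):
            for s, sign in ((h, 1.0), (-h, -1.0)):
                pos = config.positions.copy()
                pos[i, k] += s
                e, _ = potential.evaluate(config.with_positions(pos))
                f[i, k] -= sign * e
    return f / (2 * h)


# register the generic toy species used in examples and tests
register_element("X", 1.0)
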