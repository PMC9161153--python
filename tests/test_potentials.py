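"""Model potential surfaces: closed forms, gradients, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mlcmd.geometry import MolecularConfiguration
from mlcmd.potentials import (
    AnchoredOscillators,
    Harmonic1D,
    LJCoulombCluster,
    LJPair,
    Morse1D,
    PeriodicPairFluid,
    PotentialError,
    Quartic1D,
    ToyWater3,
    numeric_forces,
)


class TestOneDimensional:
    def test_harmonic_landmark(self):
        # ½mω² = 1 kJ/mol/Å² means k = 2: U(2 Å) = 4 kJ/mol, F = −4
        pot = Harmonic1D(k=2.0)
        cfg = MolecularConfiguration(["X"], np.array([[2.0, 0.0, 0.0]]))
        e, f = pot.evaluate(cfg)
        assert e == pytest.approx(4.0)
        assert f[0, 0] == pytest.approx(-4.0)
        assert np.allclose(f[0, 1:], 0.0)

    @pytest.mark.parametrize(
        "pot", [Harmonic1D(k=3.1), Quartic1D(c=7.0), Morse1D(D=120.0, a=1.7)]
    )
    def test_force_is_negative_gradient(self, pot):
        cfg = MolecularConfiguration(["X"], np.array([[0.37, 0.0, 0.0]]))
        f = pot.evaluate(cfg)[1]
        fn = numeric_forces(pot, cfg)
        assert np.allclose(f, fn, atol=1e-6)


class TestLJCoulomb:
    def test_lj_landmarks(self):
        pot = LJCoulombCluster(lj={("X", "X"): (1.0, 1.0)})
        at = lambda r: MolecularConfiguration(
            ["X", "X"], np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        )
        e_sigma, _ = pot.evaluate(at(1.0))
        assert e_sigma == pytest.approx(0.0, abs=1e-12)
        e_min, f_min = pot.evaluate(at(2.0 ** (1.0 / 6.0)))
        assert e_min == pytest.approx(-1.0)
        assert np.allclose(f_min, 0.0, atol=1e-10)

    def test_coulomb_pair_derivatives_power_law(self):
        pot = LJCoulombCluster(charges={"X": 1.0})
        u, du, d2u = pot.pair_derivatives("X", "X", 2.0)
        from mlcmd.potentials import COULOMB_K

        assert du == pytest.approx(-COULOMB_K / 4.0)
        assert d2u == pytest.approx(COULOMB_K / 4.0)

    def test_lj_pair_derivatives_at_sigma(self):
        pot = LJCoulombCluster(lj={("X", "X"): (1.0, 1.0)})
        u, du, d2u = pot.pair_derivatives("X", "X", 1.0)
        assert u == pytest.approx(0.0, abs=1e-12)
        assert du == pytest.approx(-24.0)
        assert d2u == pytest.approx(456.0)

    def test_pair_derivative_consistency_with_finite_difference(self):
        pot = LJCoulombCluster(lj={("X", "X"): (0.7, 1.3)}, charges={"X": 0.2})
        r = 1.7
        h = 1e-5
        _, du, d2u = pot.pair_derivatives("X", "X", r)
        up = pot.pair_derivatives("X", "X", r + h)[0]
        um = pot.pair_derivatives("X", "X", r - h)[0]
        assert du == pytest.approx((up - um) / (2 * h), rel=1e-7)

    def test_pairwise_energy_equals_sum_of_pair_terms(self, rng):
        pot = LJCoulombCluster(lj={("X", "X"): (0.5, 1.2)}, charges={"X": 0.3})
        pos = rng.normal(0, 2.5, (6, 3))
        cfg = MolecularConfiguration(["X"] * 6, pos)
        e, _ = pot.evaluate(cfg)
        total = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.linalg.norm(pos[i] - pos[j])
                total += pot.pair_derivatives("X", "X", r)[0]
        assert e == pytest.approx(total, rel=1e-10)

    def test_exclusions_remove_interaction(self):
        pot = LJCoulombCluster(charges={"X": 1.0}, exclusions={(0, 1)})
        cfg = MolecularConfiguration(
            ["X", "X"], np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        )
        e, f = pot.evaluate(cfg)
        assert e == 0.0 and np.all(f == 0.0)

    def test_non_pairwise_rejects_pair_derivatives(self):
        with pytest.raises(PotentialError):
            ToyWater3().pair_derivatives("O", "O", 3.0)


class TestToyWater:
    def test_forces_match_numeric_gradient(self, water_octamer):
        pot = ToyWater3()
        f = pot.evaluate(water_octamer)[1]
        fn = numeric_forces(pot, water_octamer)
        assert np.max(np.abs(f - fn)) / np.max(np.abs(fn)) < 1e-6

    def test_newtons_third_law(self, water_octamer):
        f = ToyWater3().evaluate(water_octamer)[1]
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_rigid_rotation_translation_invariance(self, water_octamer):
        pot = ToyWater3()
        e0 = pot.evaluate(water_octamer)[0]
        R = Rotation.from_euler("zyx", [0.4, -1.2, 2.0]).as_matrix()
        moved = water_octamer.with_positions(
            water_octamer.positions @ R.T + np.array([3.0, -1.0, 7.0])
        )
        e1 = pot.evaluate(moved)[0]
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_periodic_lattice_translation_invariance(self):
        cell = np.array([9.0, 9.0, 9.0])
        rng = np.random.default_rng(3)
        pos = []
        for c in [[1, 1, 1], [4.5, 4.5, 4.5], [7.5, 2.0, 6.0]]:
            c = np.array(c, dtype=float)
            pos += [c, c + [0.98, 0, 0], c + [-0.24, 0.95, 0]]
        cfg = MolecularConfiguration(
            ["O", "H", "H"] * 3, np.array(pos), cell=cell, periodic=True
        )
        pot = ToyWater3(cutoff=4.0)
        e0 = pot.evaluate(cfg)[0]
        shifted = cfg.copy()
        shifted.positions[0:3] += cell  # translate one molecule by a lattice vector
        assert pot.evaluate(shifted)[0] == pytest.approx(e0, rel=1e-10)

    def test_cutoff_beyond_half_box_is_error(self):
        cfg = MolecularConfiguration(
            ["O", "H", "H"],
            np.array([[1.0, 1, 1], [1.98, 1, 1], [0.76, 1.95, 1]]),
            cell=np.array([6.0, 6.0, 6.0]),
            periodic=True,
        )
        with pytest.raises(PotentialError):
            ToyWater3(cutoff=4.0).evaluate(cfg)


class TestPeriodicPairFluid:
    def test_minimum_image_forces(self, rng):
        pot = PeriodicPairFluid({("X", "X"): LJPair(0.5, 2.8)}, cutoff=4.0)
        # simple cubic lattice, slightly perturbed
        base = np.array(
            [[i, j, k] for i in range(2) for j in range(2) for k in range(2)],
            dtype=float,
        ) * 4.2 + 1.0
        pos = base + rng.normal(0, 0.1, base.shape)
        cfg = MolecularConfiguration(
            ["X"] * 8, pos, masses=np.full(8, 10.0),
            cell=np.array([8.4, 8.4, 8.4]), periodic=True,
        )
        f = pot.evaluate(cfg)[1]
        fn = numeric_forces(pot, cfg)
        assert np.max(np.abs(f - fn)) < 1e-5
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_energy_is_shifted_to_zero_at_cutoff(self):
        pot = PeriodicPairFluid({("X", "X"): LJPair(1.0, 2.0)}, cutoff=3.0)
        cfg = MolecularConfiguration(
            ["X", "X"], np.array([[0.0, 0, 0], [2.999, 0, 0]]),
            masses=np.array([1.0, 1.0]),
            cell=np.array([10.0, 10.0, 10.0]), periodic=True,
        )
        e, _ = pot.evaluate(cfg)
        assert abs(e) < 1e-2  # just inside the cutoff, shifted ≈ 0

    def test_uncovered_species_pair_is_error(self):
        pot = PeriodicPairFluid({("X", "X"): LJPair(1.0, 2.0)}, cutoff=3.0)
        cfg = MolecularConfiguration(
            ["X", "Y"], np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            masses=np.array([1.0, 1.0]),
            cell=np.array([10.0, 10.0, 10.0]), periodic=True,
        )
        with pytest.raises(PotentialError):
            pot.evaluate(cfg)


class TestAnchoredOscillators:
    def test_matches_base_potential_and_conserves_momentum(self, rng):
        pot = AnchoredOscillators(Quartic1D(c=10.0), k_transverse=500.0)
        anchors = np.array([[0.0, 0, 0], [0, 10.0, 0]])
        pos = np.empty((4, 3))
        pos[1::2] = anchors
        pos[0::2] = anchors + rng.normal(0, 0.3, (2, 3))
        cfg = MolecularConfiguration(
            ["H", "X", "H", "X"], pos, masses=np.array([1.008, 1e6, 1.008, 1e6])
        )
        e, f = pot.evaluate(cfg)
        fn = numeric_forces(pot, cfg)
        assert np.max(np.abs(f - fn)) < 1e-5
        assert np.abs(f.sum(axis=0)).max() < 1e-10
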