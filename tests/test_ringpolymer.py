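"""Ring-polymer state, normal modes, PIMD sampling and fixed-centroid labels."""

import numpy as np
import pytest

from mlcmd.geometry import MolecularConfiguration
from mlcmd.locality import matsubara_width
from mlcmd.potentials import Harmonic1D, Quartic1D
from mlcmd.ringpolymer import (
    PIMDIntegrator,
    RingPolymerState,
    bead_width,
    centroid,
    load_records,
    normal_mode_inverse,
    normal_mode_matrix,
    normal_mode_transform,
    sample_fixed_centroid,
    save_records,
    spring_energy,
    spring_frequency,
    virial_kinetic_energy,
)
from mlcmd.units import HBAR, KB, MECH_TO_KJMOL, wavenumber_to_angular


def one_atom_state(beads_x, T=300.0, mass=1.008):
    P = len(beads_x)
    beads = np.zeros((P, 1, 3))
    beads[:, 0, 0] = beads_x
    return RingPolymerState(beads, np.zeros((P, 1, 3)), np.array([mass]), T)


class TestCentroid:
    def test_coincident_beads(self):
        st = one_atom_state([0.7] * 8)
        assert centroid(st)[0, 0] == pytest.approx(0.7)

    def test_symmetric_pair_cancels(self):
        st = one_atom_state([0.5, -0.5])
        assert centroid(st)[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_random_state_matches_brute_force_mean(self, rng):
        beads = rng.normal(0, 1, (32, 5, 3))
        st = RingPolymerState(beads, np.zeros_like(beads), np.ones(5), 300.0)
        assert np.allclose(centroid(st), beads.mean(axis=0), atol=1e-12)


class TestSpringEnergy:
    def test_coincident_beads_zero(self):
        assert spring_energy(one_atom_state([0.3] * 16)) == pytest.approx(0.0)

    def test_two_bead_pair_of_springs(self):
        d = 0.6
        st = one_atom_state([d / 2, -d / 2], mass=1.0)
        wP = spring_frequency(2, 300.0)
        # two springs of extension d: 2·½·m·ωP²·d² = m ωP² d²
        assert spring_energy(st) == pytest.approx(
            1.0 * wP**2 * d**2 * MECH_TO_KJMOL, rel=1e-12
        )

    def test_cyclic_relabeling_invariance(self, rng):
        beads = rng.normal(0, 0.2, (16, 3, 3))
        st = RingPolymerState(beads, np.zeros_like(beads), np.ones(3), 200.0)
        rolled = RingPolymerState(
            np.roll(beads, 5, axis=0), np.zeros_like(beads), np.ones(3), 200.0
        )
        assert spring_energy(rolled) == pytest.approx(spring_energy(st), rel=1e-12)

    def test_single_bead_is_zero_by_definition(self):
        assert spring_energy(one_atom_state([0.4])) == 0.0


class TestNormalModes:
    @pytest.mark.parametrize("P", [1, 2, 3, 8, 32])
    def test_transform_roundtrip_is_identity(self, P, rng):
        beads = rng.normal(0, 1, (P, 2, 3))
        st = RingPolymerState(beads, np.zeros_like(beads), np.ones(2), 300.0)
        back = normal_mode_inverse(normal_mode_transform(st))
        assert np.allclose(back, beads, atol=1e-12)

    def test_mode_zero_is_scaled_centroid(self, rng):
        beads = rng.normal(0, 1, (16, 2, 3))
        st = RingPolymerState(beads, np.zeros_like(beads), np.ones(2), 300.0)
        modes = normal_mode_transform(st)
        assert np.allclose(modes[0] / np.sqrt(16), centroid(st), atol=1e-12)

    def test_frequencies_diagonalize_cyclic_spring_matrix(self):
        P = 8
        C, k_index = normal_mode_matrix(P)
        # cyclic tridiagonal spring matrix (in units of ωP²)
        A = 2 * np.eye(P) - np.roll(np.eye(P), 1, 1) - np.roll(np.eye(P), -1, 1)
        D = C @ A @ C.T
        assert np.allclose(D, np.diag(np.diag(D)), atol=1e-12)
        expected = (2.0 * np.sin(np.pi * k_index / P)) ** 2
        assert np.allclose(np.diag(D), expected, atol=1e-12)


@pytest.fixture
def h_config():
    return MolecularConfiguration(
        ["H"], np.array([[0.5, 0.0, 0.0]]), masses=np.array([1.008])
    )


class TestIntegrator:
    def test_free_particle_conserves_centroid_momentum_nve(self, h_config):
        integ = PIMDIntegrator(
            Harmonic1D(k=0.0), h_config, P=8, temperature=300.0,
            friction=None, rng=3,
        )
        integ.initialize()
        p0 = integ._Pm[0].copy()
        integ.step(200)
        assert np.allclose(integ._Pm[0], p0, atol=1e-12)

    def test_nve_hamiltonian_drift_small(self, h_config):
        integ = PIMDIntegrator(
            Harmonic1D(k=160.0), h_config, P=16, temperature=300.0,
            dt=0.5, friction=None, rng=5,
        )
        integ.initialize()
        H0 = integ.hamiltonian()
        drift = 0.0
        for _ in range(100):
            integ.step(100)
            drift = max(drift, abs(integ.hamiltonian() - H0))
        assert drift / abs(H0) < 1e-4

    def test_fixed_centroid_position_exactly_constant(self, h_config):
        integ = PIMDIntegrator(
            Quartic1D(c=10.0), h_config, P=16, temperature=300.0,
            fixed_centroid=True, rng=7,
        )
        integ.initialize()
        x0 = integ.centroid_positions().copy()
        integ.step(2000)
        assert np.max(np.abs(integ.centroid_positions() - x0)) < 1e-10

    def test_p1_nve_equals_hand_coded_velocity_verlet(self):
        # with one bead the integrator must be plain classical MD
        k, m, dt = 2.0, 1.008, 0.5
        cfg = MolecularConfiguration(
            ["H"], np.array([[0.8, 0.0, 0.0]]), masses=np.array([m])
        )
        integ = PIMDIntegrator(
            Harmonic1D(k=k), cfg, P=1, temperature=300.0, dt=dt,
            friction=None, rng=0,
        )
        integ.initialize(sample_momenta=False)
        integ.step(500)
        x_integ = integ.centroid_positions()[0, 0]
        # reference velocity Verlet in mechanical units
        from mlcmd.units import KJMOL_TO_MECH

        x, v = 0.8, 0.0
        f = -k * x * KJMOL_TO_MECH
        for _ in range(500):
            v += 0.5 * dt * f / m
            x += dt * v
            f = -k * x * KJMOL_TO_MECH
            v += 0.5 * dt * f / m
        assert x_integ == pytest.approx(x, abs=1e-10)

    def test_harmonic_bead_width_matches_matsubara_formula(self, h_config):
        # librational-frequency oscillator at 300 K
        omega = wavenumber_to_angular(670.0)
        pot = Harmonic1D.from_frequency(1.008, omega)
        integ = PIMDIntegrator(
            pot, h_config, P=32, temperature=300.0, dt=0.5,
            friction=5e-3, fixed_centroid=True, rng=11,
        )
        integ.initialize()
        integ.step(3000)
        widths = []
        for _ in range(40):
            block = []
            for _ in range(25):
                integ.step(6)
                block.append(integ.state)
            widths.append(bead_width(block)[0, 0])
        widths = np.array(widths)
        mean, se = widths.mean(), widths.std(ddof=1) / np.sqrt(widths.size)
        expected = matsubara_width(300.0, 1.008, 670.0)
        # 3·SE plus the ~0.5% finite-P/finite-dt allowance
        assert abs(mean - expected) < 3 * se + 0.01 * expected

    def test_virial_kinetic_energy_matches_qho(self, h_config):
        omega = wavenumber_to_angular(670.0)
        pot = Harmonic1D.from_frequency(1.008, omega)
        integ = PIMDIntegrator(
            pot, h_config, P=32, temperature=300.0, dt=0.5,
            friction=5e-3, rng=13,
        )
        integ.initialize()
        integ.step(3000)
        blocks = []
        for _ in range(20):
            samples = []
            for _ in range(40):
                integ.step(6)
                samples.append((integ.bead_positions.copy(), integ.bead_forces.copy()))
            blocks.append(virial_kinetic_energy(samples, 300.0)[0, 0])
        blocks = np.array(blocks)
        mean, se = blocks.mean(), blocks.std(ddof=1) / np.sqrt(blocks.size)
        hw = HBAR * omega  # kJ/mol
        beta = 1.0 / (KB * 300.0)
        expected = hw / 4.0 / np.tanh(beta * hw / 2.0)
        assert abs(mean - expected) < 3 * se + 0.02 * expected


class TestFixedCentroidSampling:
    def test_harmonic_mean_force_is_classical(self, h_config):
        # bead-averaged linear force equals the force at the centroid exactly
        rec = sample_fixed_centroid(
            h_config, Harmonic1D(k=2.0), 300.0, P=32, n_steps=4000, seed=17
        )
        assert rec.mean_force[0, 0] == pytest.approx(-1.0, abs=1e-10)
        assert np.allclose(rec.delta_force, 0.0, atol=1e-10)
        assert rec.metadata["centroid_drift"] < 1e-8

    def test_free_particle_mean_force_and_width(self):
        cfg = MolecularConfiguration(
            ["H"], np.zeros((1, 3)), masses=np.array([1.008])
        )
        pot = Harmonic1D(k=0.0)
        P, T = 32, 300.0
        rec = sample_fixed_centroid(cfg, pot, T, P=P, n_steps=20000, seed=19)
        assert np.all(np.abs(rec.mean_force) <= 3 * np.maximum(rec.force_sem, 1e-12))
        # measure the bead width in the same conditions
        integ = PIMDIntegrator(
            pot, cfg, P=P, temperature=T, friction=5e-3,
            fixed_centroid=True, rng=23,
        )
        integ.initialize()
        integ.step(3000)
        vals = []
        for _ in range(30):
            block = []
            for _ in range(20):
                integ.step(6)
                block.append(integ.state)
            vals.append(bead_width(block)[0].mean())
        vals = np.array(vals)
        expected = matsubara_width(T, 1.008, 0.0) * (1.0 - 1.0 / P**2)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 3 * se + 0.01 * expected

    def test_default_bead_count_policy(self):
        from mlcmd.ringpolymer import default_bead_count

        assert default_bead_count(300.0) == 32
        assert default_bead_count(100.0) == 64

    def test_record_roundtrip_through_hdf5(self, tmp_path, h_config):
        rec = sample_fixed_centroid(
            h_config, Harmonic1D(k=2.0), 300.0, P=8, n_steps=2000, seed=29
        )
        p = tmp_path / "records.h5"
        save_records(p, [rec, rec])
        back = load_records(p)
        assert len(back) == 2
        assert np.allclose(back[0].mean_force, rec.mean_force)
        assert np.allclose(back[0].force_sem, rec.force_sem)
        assert back[0].centroid.elements == rec.centroid.elements
        assert back[0].P == rec.P and back[0].converged == rec.converged

    def test_unconverged_record_is_flagged_not_dropped(self, h_config):
        rec = sample_fixed_centroid(
            h_config, Quartic1D(c=10.0), 300.0, P=16, n_steps=2000, seed=31,
            tolerance=1e-6,
        )
        assert not rec.converged

    def test_bead_width_empty_selection_is_error(self):
        st = one_atom_state([0.1, 0.2])
        with pytest.raises(ValueError):
            bead_width([st], atoms=[])
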