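"""Atomic-environment descriptors and the learned force correction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mlcmd.geometry import MolecularConfiguration
from mlcmd.mlcorrection import (
    CorrectionModel,
    DescriptorParams,
    compute_features,
    train,
)

PARAMS = DescriptorParams(cutoff=4.0, n_radial=5, L=2)


class TestDescriptors:
    def test_isolated_atom_has_zero_features(self):
        cfg = MolecularConfiguration(["H"], np.zeros((1, 3)))
        assert np.all(compute_features(cfg, PARAMS) == 0.0)

    def test_distant_atoms_have_zero_features(self):
        cfg = MolecularConfiguration(
            ["H", "H"], np.array([[0.0, 0, 0], [10.0, 0, 0]])
        )
        assert np.all(compute_features(cfg, PARAMS) == 0.0)

    def test_rotation_invariance(self, water_octamer):
        f0 = compute_features(water_octamer, PARAMS)
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        rot = water_octamer.with_positions(water_octamer.positions @ R.T)
        f1 = compute_features(rot, PARAMS)
        assert np.max(np.abs(f1 - f0)) < 1e-10 * max(np.abs(f0).max(), 1.0)

    def test_translation_invariance(self, water_octamer):
        f0 = compute_features(water_octamer, PARAMS)
        sh = water_octamer.with_positions(water_octamer.positions + [5.0, -2.0, 1.0])
        assert np.allclose(compute_features(sh, PARAMS), f0, atol=1e-10)

    def test_permutation_of_identical_elements(self, water_octamer):
        f0 = compute_features(water_octamer, PARAMS)
        pos = water_octamer.positions.copy()
        elems = list(water_octamer.elements)
        # swap the two H of the first molecule (identical species)
        pos[[1, 2]] = pos[[2, 1]]
        swapped = MolecularConfiguration(elems, pos)
        f1 = compute_features(swapped, PARAMS)
        assert np.allclose(f1[0], f0[0], atol=1e-10)  # central O unchanged
        assert np.allclose(f1[1], f0[2], atol=1e-10)

    def test_gradients_match_finite_differences(self, water_octamer):
        f0, grads = compute_features(water_octamer, PARAMS, with_gradients=True)
        h = 1e-5
        a = 4  # an H atom with several neighbors
        scale = np.abs(f0).max()
        for i in (0, 4, 7):
            for k in range(3):
                pp = water_octamer.positions.copy()
                pp[i, k] += h
                fp = compute_features(water_octamer.with_positions(pp), PARAMS)
                pm = water_octamer.positions.copy()
                pm[i, k] -= h
                fm = compute_features(water_octamer.with_positions(pm), PARAMS)
                fd = (fp[a] - fm[a]) / (2 * h)
                idx, ga = grads[a]
                analytic = np.zeros_like(fd)
                for row, j in enumerate(idx):
                    if j == i:
                        analytic += ga[row, k]
                assert np.max(np.abs(analytic - fd)) < 1e-5 * scale

    def test_smooth_at_cutoff(self):
        # feature and gradient vanish continuously as a neighbor crosses r_c
        rc = PARAMS.cutoff
        for eps in (1e-3, 1e-5):
            cfg = MolecularConfiguration(
                ["H", "H"], np.array([[0.0, 0, 0], [rc - eps, 0, 0]])
            )
            f, grads = compute_features(cfg, PARAMS, with_gradients=True)
            assert np.abs(f).max() < 1e-2
            assert np.abs(grads[0][1]).max() < 10.0 * np.sqrt(np.abs(f).max())


class TestModel:
    def test_forces_are_negative_gradient_of_scalar(self, water_octamer):
        model = CorrectionModel.create(["O", "H"], PARAMS, hidden=(8, 8), seed=1)
        F = model.predict_delta_forces(water_octamer)
        h = 1e-5
        for i in (0, 5):
            for k in range(3):
                pp = water_octamer.positions.copy()
                pp[i, k] += h
                ep = model.energy(water_octamer.with_positions(pp))
                pm = water_octamer.positions.copy()
                pm[i, k] -= h
                em = model.energy(water_octamer.with_positions(pm))
                assert -(ep - em) / (2 * h) == pytest.approx(
                    F[i, k], abs=1e-5 * max(np.abs(F).max(), 1.0)
                )

    def test_total_correction_force_vanishes(self, water_octamer):
        model = CorrectionModel.create(["O", "H"], PARAMS, hidden=(8, 8), seed=2)
        F = model.predict_delta_forces(water_octamer)
        assert np.abs(F.sum(axis=0)).max() < 1e-8

    def test_rotational_equivariance(self, water_octamer):
        model = CorrectionModel.create(["O", "H"], PARAMS, hidden=(8, 8), seed=3)
        F = model.predict_delta_forces(water_octamer)
        R = Rotation.from_euler("zxz", [1.0, 0.5, -0.2]).as_matrix()
        rot = water_octamer.with_positions(water_octamer.positions @ R.T)
        Frot = model.predict_delta_forces(rot)
        assert np.max(np.abs(Frot - F @ R.T)) < 1e-8 * max(np.abs(F).max(), 1.0)

    def test_locality_perturbation_beyond_cutoff(self):
        # two anchored pairs 12 Å apart: moving the far pair cannot change
        # the near pair's correction at all
        pos = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [12.0, 0, 0], [13.0, 0, 0]]
        )
        cfg = MolecularConfiguration(["H", "H", "H", "H"], pos)
        model = CorrectionModel.create(["H"], PARAMS, hidden=(8,), seed=4)
        F0 = model.predict_delta_forces(cfg)[:2]
        moved = pos.copy()
        moved[3] += [0.4, 0.3, -0.2]
        F1 = model.predict_delta_forces(cfg.with_positions(moved))[:2]
        assert np.max(np.abs(F1 - F0)) < 1e-12

    def test_unknown_element_is_error(self, water_octamer):
        model = CorrectionModel.create(["H"], PARAMS, hidden=(4,), seed=5)
        with pytest.raises(KeyError):
            model.predict_delta_forces(water_octamer)

    def test_save_load_roundtrip(self, tmp_path, water_octamer):
        model = CorrectionModel.create(["O", "H"], PARAMS, hidden=(6, 6), seed=6)
        model.feat_shift = np.linspace(0, 1, PARAMS.n_features)
        model.feat_scale = np.linspace(1, 2, PARAMS.n_features)
        p = tmp_path / "model.json"
        model.save(p)
        back = CorrectionModel.load(p)
        F0 = model.predict_delta_forces(water_octamer)
        F1 = back.predict_delta_forces(water_octamer)
        assert np.allclose(F0, F1, atol=1e-12)


class TestTraining:
    def _configs(self, rng, n):
        from conftest import make_water_cluster

        return [make_water_cluster(rng, n_molecules=4) for _ in range(n)]

    def test_zero_labels_give_null_model(self, rng):
        cfgs = self._configs(rng, 12)
        records = [(c, np.zeros((c.n_atoms, 3))) for c in cfgs]
        model = train(records, params=PARAMS, hidden=(6,), seed=7, max_lm_iters=5)
        held = self._configs(rng, 4)
        rms = np.sqrt(
            np.mean(
                np.concatenate(
                    [model.predict_delta_forces(c).ravel() for c in held]
                )
                ** 2
            )
        )
        assert rms <= 1e-3

    def test_training_is_bitwise_reproducible(self, rng):
        cfgs = self._configs(rng, 8)
        teacher = CorrectionModel.create(["O", "H"], PARAMS, hidden=(4,), seed=8)
        records = [(c, teacher.predict_delta_forces(c)) for c in cfgs]
        m1 = train(records, params=PARAMS, hidden=(6,), seed=9, max_lm_iters=3)
        m2 = train(records, params=PARAMS, hidden=(6,), seed=9, max_lm_iters=3)
        for e in m1.elements:
            assert np.array_equal(m1.nets[e].get_flat(), m2.nets[e].get_flat())

    def test_too_few_records_is_error(self):
        with pytest.raises(ValueError):
            train([], params=PARAMS)
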