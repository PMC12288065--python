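"""Loss definitions, weight calibration, fitting, evaluation, learning curve."""

import numpy as np
import pytest

from hesspot.derivatives import DerivativeBundle, predict_bundle
from hesspot.descriptor import AEVSpec
from hesspot.model import featurize_structures
from hesspot.structures import LabeledStructure, build_batch, mask_counts
from hesspot.surfaces import label_structure, morse_diatomic
from hesspot.training import (LossWeights, TrainConfig, TrainingError,
                              calibrate_weights, evaluate_rmse, fit,
                              learning_curve, loss_terms, total_loss)


def _labeled(n, seed):
    rng = np.random.default_rng(seed)
    H = rng.standard_normal((3 * n, 3 * n))
    return LabeledStructure(("H",) * n, rng.standard_normal((n, 3)),
                            energy=float(rng.standard_normal()),
                            forces=rng.standard_normal((n, 3)),
                            hessian=H + H.T)


def _bundle_from(batch, energies=None, forces=None, hessians=None):
    return DerivativeBundle(
        batch.energies.copy() if energies is None else energies,
        batch.forces.copy() if forces is None else forces,
        batch.hessians.copy() if hessians is None else hessians,
        batch.atom_mask.copy())


class TestLossTerms:
    def test_perfect_predictions_zero(self):
        batch = build_batch([_labeled(2, 0), _labeled(3, 1)])
        assert loss_terms(_bundle_from(batch), batch) == (0.0, 0.0, 0.0)

    def test_single_energy_residual(self):
        batch = build_batch([_labeled(2, 2)])
        pred = _bundle_from(batch, energies=batch.energies + 2.0)
        eps = loss_terms(pred, batch)
        assert eps == (pytest.approx(2.0), 0.0, 0.0)

    def test_hand_built_batch_matches_explicit_summation(self):
        # 2 molecules x 2 atoms: recompute the RMSE sums by hand
        structures = [_labeled(2, 3), _labeled(2, 4)]
        batch = build_batch(structures)
        rng = np.random.default_rng(9)
        dE = rng.standard_normal(2)
        dF = rng.standard_normal((2, 2, 3))
        dH = rng.standard_normal((2, 6, 6))
        pred = _bundle_from(batch, energies=batch.energies + dE,
                            forces=batch.forces + dF,
                            hessians=batch.hessians + dH)
        eps_e, eps_f, eps_h = loss_terms(pred, batch)
        M, n_f, n_h = mask_counts(batch)
        assert (M, n_f, n_h) == (2, 12, 72)
        assert eps_e == pytest.approx(np.sqrt((dE ** 2).sum() / M), rel=1e-12)
        assert eps_f == pytest.approx(np.sqrt((dF ** 2).sum() / n_f), rel=1e-12)
        assert eps_h == pytest.approx(np.sqrt((dH ** 2).sum() / n_h), rel=1e-12)

    def test_mask_mismatch_rejected(self):
        b1 = build_batch([_labeled(2, 5)])
        b2 = build_batch([_labeled(3, 6)])
        with pytest.raises(TrainingError, match="mask"):
            loss_terms(_bundle_from(b1), b2)


class TestTotalLoss:
    def test_weighted_sum_with_default_weights(self):
        # eps = (1, 10, 50), weights (0.08, 0.02) -> 1 + 0.8 + 1.0
        assert total_loss((1.0, 10.0, 50.0), LossWeights(0.08, 0.02)) \
            == pytest.approx(2.8)

    def test_energy_only(self):
        assert total_loss((1.5, 99.0, 99.0), LossWeights(0, 0)) == 1.5

    def test_zero_terms(self):
        assert total_loss((0.0, 0.0, 0.0), LossWeights(0.08, 0.02)) == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(TrainingError):
            LossWeights(-0.1, 0.0)


class TestCalibrateWeights:
    def test_reference_ratios_give_default_weights(self):
        w = calibrate_weights((1.0, 12.5, 50.0))
        assert (w.eta_f, w.eta_h) == (pytest.approx(0.08), pytest.approx(0.02))

    def test_equal_finals_give_unit_weights(self):
        w = calibrate_weights((2.0, 2.0, 2.0))
        assert (w.eta_f, w.eta_h) == (1.0, 1.0)

    def test_doubling_ratios(self):
        w = calibrate_weights((2.0, 4.0, 8.0))
        assert (w.eta_f, w.eta_h) == (0.5, 0.25)

    def test_zero_denominator_rejected(self):
        with pytest.raises(TrainingError):
            calibrate_weights((1.0, 0.0, 50.0))


@pytest.fixture(scope="module")
def morse_setup():
    ff = morse_diatomic(80.0, 2.0, 1.1, species=("O", "H"))
    rs = np.linspace(0.9, 1.6, 25)
    structures = [label_structure(ff, np.array([[0, 0, 0], [r, 0, 0]]))
                  for r in rs]
    spec = AEVSpec(elements=("H", "O"),
                   radial_shifts=tuple(np.linspace(0.7, 2.2, 8)),
                   angular_theta_shifts=(0.0, np.pi / 2),
                   angular_radial_shifts=(1.0, 1.8))
    fb = featurize_structures(structures, spec, 2)
    return spec, fb, structures


class TestFit:
    def test_recovers_morse_surface_with_efh_loss(self, morse_setup):
        spec, fb, structures = morse_setup
        cfg = TrainConfig(hidden=(24, 24), lr=5e-3, epochs=400, seed=1)
        model, report = fit(fb, LossWeights(0.08, 0.02), cfg, spec=spec)
        b = predict_bundle(model, structures, order=2)
        batch = build_batch(structures)
        eps_e, eps_f, eps_h = loss_terms(b, batch)
        f_rms = np.sqrt((fb.forces_flat ** 2).mean())
        h_rms = np.sqrt((fb.hessians ** 2).mean())
        assert eps_f < 0.05 * f_rms
        assert eps_h < 0.05 * h_rms

    def test_missing_hessians_with_hessian_loss_rejected(self, morse_setup):
        spec, fb, structures = morse_setup
        no_hess = [LabeledStructure(s.species, s.coordinates, energy=s.energy,
                                    forces=s.forces) for s in structures]
        with pytest.raises(TrainingError, match="Hessian"):
            fit(no_hess, LossWeights(0.08, 0.02),
                TrainConfig(epochs=1), spec=spec)

    def test_deterministic_given_seed(self, morse_setup):
        spec, fb, _ = morse_setup
        cfg = TrainConfig(hidden=(8, 8), lr=5e-3, epochs=30, seed=4)
        _, r1 = fit(fb, LossWeights(0.08, 0.0), cfg, spec=spec)
        _, r2 = fit(fb, LossWeights(0.08, 0.0), cfg, spec=spec)
        assert np.array_equal(r1.history["train_loss"], r2.history["train_loss"])
        assert r1.final_train == r2.final_train


class TestEvaluateRMSE:
    def test_identical_members_zero_std(self, morse_setup):
        spec, fb, _ = morse_setup
        cfg = TrainConfig(hidden=(8, 8), epochs=20, seed=0)
        model, _ = fit(fb, LossWeights(0.08, 0.02), cfg, spec=spec)
        from hesspot.model import Ensemble
        ens = Ensemble([model, model], [0, 0])
        ev = evaluate_rmse(ens, fb)
        assert all(v == 0.0 for v in ev.std.values())

    def test_single_model_report(self, morse_setup):
        spec, fb, _ = morse_setup
        cfg = TrainConfig(hidden=(8, 8), epochs=20, seed=0)
        model, _ = fit(fb, LossWeights(0.08, 0.02), cfg, spec=spec)
        ev = evaluate_rmse(model, fb)
        assert len(ev.per_member) == 1

    def test_matches_loss_terms_per_member(self, morse_setup):
        spec, fb, structures = morse_setup
        cfg = TrainConfig(hidden=(8, 8), epochs=20, seed=0)
        model, _ = fit(fb, LossWeights(0.08, 0.02), cfg, spec=spec)
        ev = evaluate_rmse(model, fb)
        b = predict_bundle(model, structures, order=2)
        eps = loss_terms(b, build_batch(structures))
        assert ev.mean["energy_rmse"] == pytest.approx(eps[0], rel=1e-9)
        assert ev.mean["hessian_rmse"] == pytest.approx(eps[2], rel=1e-9)


class TestLearningCurve:
    def test_mechanics_and_nesting(self, morse_setup):
        spec, fb, structures = morse_setup
        cfg = TrainConfig(hidden=(8, 8), epochs=15, seed=0)
        df = learning_curve(fb, [0.5, 1.0], [LossWeights(0.08, 0.0)],
                            seed=3, test_set=structures[:5], config=cfg,
                            spec=spec)
        assert set(df["fraction"]) == {0.5, 1.0}
        assert df[df.fraction == 1.0].iloc[0]["n_train"] == fb.n_mol

    def test_fraction_below_one_molecule_rejected(self, morse_setup):
        spec, fb, structures = morse_setup
        with pytest.raises(TrainingError):
            learning_curve(fb, [1e-4], [LossWeights(0, 0)], seed=0,
                           test_set=structures[:2],
                           config=TrainConfig(epochs=1), spec=spec)
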