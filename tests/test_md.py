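"""Langevin MD and the iterative-heating stability protocol."""

import math

import numpy as np
import pytest

from hesspot.md import (MDState, RampProtocol, failure_check,
                        kinetic_temperature, langevin_stage,
                        maxwell_boltzmann_velocities, temperature_ramp)
from hesspot.structures import LabeledStructure
from hesspot.surfaces import (TriatomicFamily, find_critical_point,
                              morse_diatomic, _bent_geometry)


class _ZeroForce:
    def energy_and_forces(self, structure):
        return 0.0, np.zeros_like(structure.coordinates)


@pytest.fixture(scope="module")
def reaction_ff():
    fam = TriatomicFamily()
    ff, params = fam.reaction_ff(("H", "C", "O"))
    th1 = math.radians(params["theta_deg"][0])
    r1, r2 = params["r0"]
    minimum = find_critical_point(ff, _bent_geometry(r1, r2, th1), "minimum")
    return ff, minimum


class TestLangevinStage:
    def test_zero_force_near_zero_temperature_stationary(self):
        proto = RampProtocol(seed=0)
        s = LabeledStructure(("O", "H"), np.array([[0., 0, 0], [1.1, 0, 0]]))
        masses = s.masses
        state = MDState(s.coordinates.copy(), np.zeros((2, 3)),
                        np.zeros((2, 3)))
        rng = np.random.default_rng(0)
        out = langevin_stage(_ZeroForce(), s.species, state, masses,
                             1e-12, proto, rng, n_steps=100)
        assert np.abs(out.coords - s.coordinates).max() < 1e-6

    def test_equipartition_on_exact_diatomic(self):
        # time-averaged kinetic temperature within 15% of target over 5 ps
        ff = morse_diatomic(100.0, 2.0, 1.1, species=("O", "H"))
        s = LabeledStructure(("O", "H"), np.array([[0., 0, 0], [1.1, 0, 0]]))
        masses = s.masses
        proto = RampProtocol(seed=1)
        rng = np.random.default_rng(42)
        state = MDState(s.coordinates.copy(),
                        maxwell_boltzmann_velocities(masses, 300.0, rng),
                        ff.energy_and_forces(s)[1])
        # instantaneous kinetic T of 6 DOF fluctuates ~40% and the energy
        # envelope relaxes on the 1/friction scale, so average over a long
        # window (20 ps) sampled every 10 steps
        temps = []
        for _ in range(4000):
            state = langevin_stage(ff, s.species, state, masses, 300.0,
                                   proto, rng, n_steps=10)
            temps.append(kinetic_temperature(state.velocities, masses))
        assert np.mean(temps) == pytest.approx(300.0, rel=0.15)

    def test_same_seed_identical_trajectory(self):
        ff = morse_diatomic(100.0, 2.0, 1.1, species=("O", "H"))
        s = LabeledStructure(("O", "H"), np.array([[0., 0, 0], [1.1, 0, 0]]))
        masses = s.masses
        proto = RampProtocol(seed=0)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            state = MDState(s.coordinates.copy(), np.zeros((2, 3)),
                            ff.energy_and_forces(s)[1])
            outs.append(langevin_stage(ff, s.species, state, masses, 100.0,
                                       proto, rng, n_steps=200).coords)
        assert np.array_equal(outs[0], outs[1])


class TestFailureCheck:
    def test_constant_equilibrium_no_failure(self):
        window = np.full((50, 2), 1.0)
        failed, _, _ = failure_check(window, np.array([1.0, 1.0]))
        assert not failed

    def test_stretched_pair_fails(self):
        window = np.full((50, 2), 1.0)
        window[:, 1] = 1.6
        failed, pair, direction = failure_check(window, np.array([1.0, 1.0]))
        assert failed and pair == 1 and direction == "stretch"

    def test_exact_threshold_is_not_failure(self):
        # strict inequality: mean distance exactly 1.5 d_eq passes
        window = np.full((50, 1), 1.5)
        failed, _, _ = failure_check(window, np.array([1.0]))
        assert not failed

    def test_compression_detected(self):
        window = np.full((50, 1), 0.7)
        failed, _, direction = failure_check(window, np.array([1.0]))
        assert failed and direction == "compression"

    def test_window_length_enforced(self):
        with pytest.raises(ValueError, match="50"):
            failure_check(np.ones((49, 1)), np.array([1.0]))

    def test_purity(self):
        window = np.full((50, 1), 1.2)
        a = failure_check(window, np.array([1.0]))
        b = failure_check(window, np.array([1.0]))
        assert a == b


class TestTemperatureRamp:
    def test_exact_ff_control_reaches_cap(self, reaction_ff):
        ff, minimum = reaction_ff
        proto = RampProtocol(start_temperature=50.0, increment=100.0,
                             stage_ps=0.1, temperature_cap=250.0, seed=3)
        res = temperature_ramp(ff, minimum, proto, bonds=ff.bonded_pairs)
        assert res.cap_reached
        assert res.failure_temperature is None

    def test_zero_force_model_fails_early(self, reaction_ff):
        # free diffusion breaks the bond-distortion criterion quickly
        ff, minimum = reaction_ff
        proto = RampProtocol(start_temperature=50.0, increment=50.0,
                             stage_ps=0.5, temperature_cap=400.0, seed=4)
        res = temperature_ramp(_ZeroForce(), minimum, proto,
                               bonds=ff.bonded_pairs)
        assert res.failed_on_optimization or \
            (res.failure_temperature is not None
             and res.failure_temperature <= 100.0)

    def test_seeded_repeat_identical(self, reaction_ff):
        ff, minimum = reaction_ff
        proto = RampProtocol(start_temperature=100.0, increment=100.0,
                             stage_ps=0.05, temperature_cap=200.0, seed=5)
        r1 = temperature_ramp(ff, minimum, proto, bonds=ff.bonded_pairs)
        r2 = temperature_ramp(ff, minimum, proto, bonds=ff.bonded_pairs)
        assert r1 == r2
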