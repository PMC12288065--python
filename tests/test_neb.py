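"""Climbing-image NEB on analytic surfaces with exact barriers."""

import numpy as np
import pytest

from hesspot.neb import (MEP, NEBError, barrier_height, interpolate_path,
                         optimize_mep)
from hesspot.structures import LabeledStructure
from hesspot.surfaces import (eval_reference, find_critical_point,
                              mueller_brown, quartic_double_well)


@pytest.fixture(scope="module")
def double_well_endpoints():
    ff = quartic_double_well()
    r = find_critical_point(ff, np.array([[-0.9, 0, 0]]), "minimum")
    p = find_critical_point(ff, np.array([[0.9, 0, 0]]), "minimum")
    return ff, r, p


class TestInterpolation:
    def test_three_images_midpoint_average(self):
        a = LabeledStructure(("H",), np.zeros((1, 3)))
        b = LabeledStructure(("H",), np.ones((1, 3)))
        images = interpolate_path(a, b, 3)
        assert np.allclose(images[1].coordinates, 0.5)
        assert np.array_equal(images[0].coordinates, a.coordinates)
        assert np.array_equal(images[2].coordinates, b.coordinates)

    def test_identical_endpoints_identical_images(self):
        a = LabeledStructure(("H",), np.zeros((1, 3)))
        for im in interpolate_path(a, a, 5):
            assert np.array_equal(im.coordinates, a.coordinates)

    def test_fractional_positions(self):
        a = LabeledStructure(("H", "H"), np.zeros((2, 3)))
        b = LabeledStructure(("H", "H"), np.full((2, 3), 2.0))
        images = interpolate_path(a, b, 5)
        for k, im in enumerate(images):
            f = k / 4
            assert np.allclose(im.coordinates, 2.0 * f)

    def test_species_mismatch_rejected(self):
        a = LabeledStructure(("H",), np.zeros((1, 3)))
        b = LabeledStructure(("O",), np.ones((1, 3)))
        with pytest.raises(NEBError, match="species"):
            interpolate_path(a, b, 3)


class TestOptimizeMEP:
    def test_double_well_barrier_exact(self, double_well_endpoints):
        # V = x^4 - 2x^2: barrier from minimum (-1) to saddle (0) is exactly 1
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 16),
                           fmax_tol_ev=0.002)
        assert mep.converged
        assert barrier_height(mep) == pytest.approx(1.0, rel=0.02)

    def test_mueller_brown_ci_matches_saddle_oracle(self):
        ff = mueller_brown()
        m1 = find_critical_point(ff, np.array([[-0.5, 1.5, 0]]), "minimum")
        m2 = find_critical_point(ff, np.array([[0.0, 0.5, 0]]), "minimum")
        saddle = find_critical_point(ff, np.array([[-0.8, 0.6, 0]]), "saddle1")
        mep = optimize_mep(ff, interpolate_path(m1, m2, 16))
        assert mep.converged
        ci_energy = mep.energies.max()
        assert abs(ci_energy - saddle.energy) < 0.01 * abs(saddle.energy)

    def test_ci_image_is_first_order_saddle(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 16), fmax_tol_ev=0.002)
        ci = mep.images[int(np.argmax(mep.energies))]
        _, f, h = eval_reference(ff, ci.coordinates)
        assert np.abs(f).max() < 0.1
        assert (np.linalg.eigvalsh(h) < -1e-3).sum() == 1

    def test_endpoints_unchanged(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 10))
        assert np.array_equal(mep.images[0].coordinates, r.coordinates)
        assert np.array_equal(mep.images[-1].coordinates, p.coordinates)

    def test_nonconvergence_reported_not_hidden(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 10), max_iterations=2)
        assert not mep.converged
        assert mep.final_fmax > 0

    def test_doubling_images_stable_barrier(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        b1 = barrier_height(optimize_mep(ff, interpolate_path(r, p, 12),
                                         fmax_tol_ev=0.002))
        b2 = barrier_height(optimize_mep(ff, interpolate_path(r, p, 24),
                                         fmax_tol_ev=0.002))
        assert abs(b1 - b2) / b1 < 0.005


class TestBarrierHeight:
    def test_symmetric_well_same_from_both_ends(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 14), fmax_tol_ev=0.002)
        assert barrier_height(mep, "reactant") == pytest.approx(
            barrier_height(mep, "product"), abs=1e-6)

    def test_monotone_profile_equals_endpoint_difference(self):
        energies = np.array([0.0, 1.0, 2.0, 3.0])
        mep = MEP([None] * 4, energies, np.arange(4.0), 50.0, True, 0.0)
        assert barrier_height(mep, "reactant") == 3.0
        assert barrier_height(mep, "product") == 0.0

    def test_matches_external_arithmetic(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 12), fmax_tol_ev=0.002)
        assert barrier_height(mep, "reactant") == pytest.approx(
            float(mep.energies.max() - mep.energies[0]))

    def test_unconverged_requires_force(self, double_well_endpoints):
        ff, r, p = double_well_endpoints
        mep = optimize_mep(ff, interpolate_path(r, p, 10), max_iterations=2)
        with pytest.raises(NEBError):
            barrier_height(mep)
        barrier_height(mep, force=True)   # explicit override allowed
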