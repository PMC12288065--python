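"""Descriptor: symmetry-function values, invariances, smoothness, derivatives."""

import numpy as np
import pytest

from hesspot.descriptor import (AEVSpec, DescriptorError, compute_aev,
                                featurize_structure, _cutoff)
from hesspot.structures import LabeledStructure, build_batch


class TestValues:
    def test_isolated_atom_is_zero(self, small_spec):
        s = LabeledStructure(("H",), np.zeros((1, 3)))
        G, _, _ = featurize_structure(s, small_spec, order=0)
        assert np.all(G == 0.0)

    def test_diatomic_beyond_cutoff_is_zero(self, small_spec):
        s = LabeledStructure(("H", "H"),
                             np.array([[0, 0, 0], [small_spec.cutoff, 0, 0]]))
        G, _, _ = featurize_structure(s, small_spec, order=0)
        assert np.all(G == 0.0)

    def test_radial_term_matches_hand_summed_formula(self, small_spec, triatomic):
        # recompute one radial channel of atom 1 (C) by direct summation
        G, _, _ = featurize_structure(triatomic, small_spec, order=0)
        coords = triatomic.coordinates
        spec = small_spec
        rs_index = 2
        Rs = spec.radial_shifts[rs_index]
        # channel: neighbors of element H around atom 1
        h_idx = spec.elements.index("H")
        expected = 0.0
        for j, el in enumerate(triatomic.species):
            if j == 1 or el != "H":
                continue
            r = np.linalg.norm(coords[j] - coords[1])
            if r < spec.cutoff:
                fc = (1 - (r / spec.cutoff) ** 2) ** 3
                expected += np.exp(-spec.eta_radial * (r - Rs) ** 2) * fc
        assert G[1, h_idx * spec.n_radial + rs_index] == pytest.approx(expected, rel=1e-12)

    def test_unknown_element_named_in_error(self, small_spec):
        s = LabeledStructure(("H", "U"), np.array([[0., 0, 0], [1, 0, 0]]),
                             info={})
        # bypass mass lookup by building structure with a fake species list
        with pytest.raises(DescriptorError, match="U"):
            featurize_structure(s, small_spec, order=0)


class TestInvariances:
    def test_rotation_invariance(self, small_spec, bent_molecule):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        G0, _, _ = featurize_structure(bent_molecule, small_spec, order=0)
        rot = LabeledStructure(bent_molecule.species,
                               bent_molecule.coordinates @ Q.T)
        G1, _, _ = featurize_structure(rot, small_spec, order=0)
        assert np.abs(G0 - G1).max() < 1e-10

    def test_swapping_identical_atoms_reorders_rows(self, small_spec, bent_molecule):
        # atoms 2 and 3 are both hydrogens
        G0, _, _ = featurize_structure(bent_molecule, small_spec, order=0)
        coords = bent_molecule.coordinates[[0, 1, 3, 2]]
        swapped = LabeledStructure(bent_molecule.species, coords)
        G1, _, _ = featurize_structure(swapped, small_spec, order=0)
        assert np.allclose(G0[[0, 1, 3, 2]], G1, atol=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("order,step,tol", [(1, 1e-5, 1e-7), (2, 1e-4, 1e-5)])
    def test_match_finite_differences(self, small_spec, bent_molecule,
                                      order, step, tol):
        G, dG, d2G = featurize_structure(bent_molecule, small_spec, order=2)
        target = dG if order == 1 else d2G
        scale = np.abs(target).max()
        n = bent_molecule.n_atoms
        for a in range(n):
            for d in range(3):
                cp = bent_molecule.coordinates.copy()
                cm = cp.copy()
                cp[a, d] += step
                cm[a, d] -= step
                up = featurize_structure(
                    LabeledStructure(bent_molecule.species, cp), small_spec,
                    order - 1)[order - 1]
                um = featurize_structure(
                    LabeledStructure(bent_molecule.species, cm), small_spec,
                    order - 1)[order - 1]
                fd = (up - um) / (2 * step)
                assert np.abs(fd - target[..., 3 * a + d]).max() < tol * max(scale, 1.0)

    def test_second_derivative_symmetric(self, small_spec, bent_molecule):
        _, _, d2G = featurize_structure(bent_molecule, small_spec, order=2)
        assert np.abs(d2G - d2G.transpose(0, 1, 3, 2)).max() < 1e-12


class TestCutoffSmoothness:
    def test_smooth_poly_is_c2_at_cutoff(self, small_spec):
        rc = small_spec.cutoff
        r = np.array([rc - 1e-9, rc - 1e-12])
        f, f1, f2 = _cutoff(r, small_spec)
        # value, slope, and curvature all approach zero at Rc
        assert np.abs(f).max() < 1e-15
        assert np.abs(f1).max() < 1e-8
        assert np.abs(f2).max() < 1e-8

    def test_cosine_cutoff_has_curvature_jump(self):
        spec = AEVSpec(cutoff_fn="cosine")
        rc = spec.cutoff
        _, _, f2_in = _cutoff(np.array([rc - 1e-9]), spec)
        _, _, f2_out = _cutoff(np.array([rc + 1e-9]), spec)
        assert abs(f2_in[0] - f2_out[0]) > 0.1   # the kink the default avoids

    def test_descriptor_derivative_continuous_across_cutoff(self, small_spec):
        # diatomic crossing Rc: first derivatives stay continuous
        rc = small_spec.cutoff
        vals = []
        for r in (rc - 1e-4, rc + 1e-4):
            s = LabeledStructure(("H", "H"), np.array([[0., 0, 0], [r, 0, 0]]))
            _, dG, _ = featurize_structure(s, small_spec, order=1)
            vals.append(dG)
        assert np.abs(vals[0] - vals[1]).max() < 1e-6


def test_compute_aev_padded_rows_zero(small_spec):
    a = LabeledStructure(("H", "O"), np.array([[0., 0, 0], [1.0, 0, 0]]))
    b = LabeledStructure(("H", "C", "O"),
                         np.array([[1.2, 0, 0], [0., 0, 0], [-0.3, 1.1, 0]]))
    batch = build_batch([a, b])
    aev = compute_aev(batch, small_spec)
    assert aev.values.shape == (2, 3, small_spec.length)
    assert np.all(aev.values[0, 2] == 0.0)
    assert aev.values[1].any()


def test_descriptor_length_formula(small_spec):
    ne = small_spec.n_elements
    expected = (ne * small_spec.n_radial
                + ne * (ne + 1) // 2 * small_spec.n_angular)
    assert small_spec.length == expected
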