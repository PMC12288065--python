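"""Analytic surfaces: label consistency, critical points, IRC, RTP family."""

import numpy as np
import pytest

from hesspot.surfaces import (SaddleIndexError, TriatomicFamily,
                              build_rtp_dataset, eval_reference,
                              find_critical_point, hessian_index,
                              morse_diatomic, mueller_brown,
                              quartic_double_well, trace_irc)


@pytest.fixture(scope="module")
def family():
    return TriatomicFamily()


@pytest.fixture(scope="module")
def rtp(family):
    return build_rtp_dataset(family, 6, seed=3)


class TestEvalReference:
    def test_morse_diatomic_at_equilibrium(self):
        # minimum of D(1-exp(-a(r-r0)))^2: E=0, F=0, stretch curvature 2 D a^2
        ff = morse_diatomic(depth=1.0, width=1.0, r0=1.0)
        e, f, h = eval_reference(ff, np.array([[0, 0, 0], [1.0, 0, 0]]))
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)
        assert h[0, 0] == pytest.approx(2.0, abs=1e-10)

    def test_double_well_saddle_curvature(self):
        # V = x^4 - 2 x^2 at x=0: E=0, F=0, curvature -4
        ff = quartic_double_well()
        e, f, h = eval_reference(ff, np.zeros((1, 3)))
        assert e == 0.0
        assert np.abs(f).max() == 0.0
        assert h[0, 0] == pytest.approx(-4.0)

    def test_gradient_hessian_match_finite_differences(self, family):
        ff, _ = family.reaction_ff(("H", "C", "O"))
        x = np.array([[1.15, 0.1, 0.04], [0, 0, 0], [-0.35, 1.2, -0.1]])
        e0, g0, H0 = ff.evaluate(x, order=2)
        step = 1e-5
        gmax = np.abs(g0).max()
        for a in range(3):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, d] += step
                xm[a, d] -= step
                fd = (ff.evaluate(xp, 0)[0] - ff.evaluate(xm, 0)[0]) / (2 * step)
                assert abs(fd - g0[a, d]) < 1e-6 * max(1.0, gmax)
                fdh = (ff.evaluate(xp, 1)[1] - ff.evaluate(xm, 1)[1]).ravel() / (2 * step)
                assert np.abs(fdh - H0[3 * a + d]).max() < 1e-6 * np.abs(H0).max()

    def test_atom_count_mismatch_raises(self):
        ff = morse_diatomic()
        with pytest.raises(Exception, match="atoms"):
            ff.evaluate(np.zeros((3, 3)))


class TestFindCriticalPoint:
    def test_double_well_minimum(self):
        ff = quartic_double_well()
        s = find_critical_point(ff, np.array([[0.5, 0, 0]]), "minimum")
        assert s.coordinates[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert s.energy == pytest.approx(-1.0, abs=1e-9)

    def test_double_well_saddle(self):
        ff = quartic_double_well()
        s = find_critical_point(ff, np.array([[0.1, 0, 0]]), "saddle1")
        assert s.coordinates[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert s.energy == pytest.approx(0.0, abs=1e-9)

    def test_mueller_brown_minimum_matches_grid_oracle(self):
        ff = mueller_brown()
        s = find_critical_point(ff, np.array([[-0.5, 1.5, 0]]), "minimum")
        # independent oracle: dense grid + local quadratic refinement
        xs = np.linspace(-1.0, 0.0, 101)
        ys = np.linspace(1.0, 2.0, 101)
        E = np.array([[ff.evaluate(np.array([[x, y, 0.0]]), 0)[0] for x in xs]
                      for y in ys])
        iy, ix = np.unravel_index(np.argmin(E), E.shape)
        assert abs(s.coordinates[0, 0] - xs[ix]) < 0.02
        assert abs(s.coordinates[0, 1] - ys[iy]) < 0.02
        assert s.energy <= E.min() + 1e-6

    def test_wrong_index_raises(self):
        ff = quartic_double_well()
        # seeking a saddle starting deep inside a well converges to the
        # minimum -> index mismatch must be reported, not hidden
        with pytest.raises(SaddleIndexError):
            find_critical_point(ff, np.array([[1.4, 0.0, 0.0]]), "saddle1",
                                trust=0.01, maxiter=2000)

    def test_forces_below_tolerance_at_convergence(self, rtp):
        for r in rtp.reactions[:3]:
            for s in (r.reactant, r.ts, r.product):
                _, f, _ = eval_reference(r.ff, s.coordinates)
                assert np.abs(f).max() < 1e-3


class TestTraceIRC:
    def test_double_well_path_symmetric(self):
        ff = quartic_double_well()
        sd = find_critical_point(ff, np.array([[0.1, 0, 0]]), "saddle1")
        path = trace_irc(ff, sd)
        assert path.images[path.ts_index].coordinates[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert path.arc[path.ts_index] == 0.0
        assert path.energies[0] == pytest.approx(-1.0, abs=1e-4)
        assert path.energies[-1] == pytest.approx(-1.0, abs=1e-4)
        # arc strictly increasing, exactly one zero
        assert np.all(np.diff(path.arc) > 0)
        assert np.count_nonzero(path.arc == 0.0) == 1

    def test_energies_monotone_away_from_ts(self):
        ff = quartic_double_well()
        sd = find_critical_point(ff, np.array([[0.1, 0, 0]]), "saddle1")
        path = trace_irc(ff, sd)
        E = path.energies
        k = path.ts_index
        assert np.all(np.diff(E[: k + 1]) >= -1e-9)          # rising into TS
        assert np.all(np.diff(E[k:]) <= 1e-9)                # falling after TS

    def test_mueller_brown_endpoints_match_minima(self):
        ff = mueller_brown()
        sd = find_critical_point(ff, np.array([[-0.8, 0.6, 0]]), "saddle1")
        path = trace_irc(ff, sd, max_images_per_branch=25)
        m1 = find_critical_point(ff, path.images[0].coordinates, "minimum")
        m2 = find_critical_point(ff, path.images[-1].coordinates, "minimum")
        assert path.energies[0] == pytest.approx(m1.energy, abs=1e-3)
        assert path.energies[-1] == pytest.approx(m2.energy, abs=1e-3)
        ends = sorted([m1.energy, m2.energy])
        # the two adjacent Mueller-Brown minima found independently
        mA = find_critical_point(ff, np.array([[-0.56, 1.44, 0]]), "minimum")
        mB = find_critical_point(ff, np.array([[0.0, 0.5, 0]]), "minimum")
        assert ends == pytest.approx(sorted([mA.energy, mB.energy]), abs=1e-6)

    def test_arc_reparametrization_consistent(self):
        # halving the integration step changes interpolated per-image
        # energies by less than 1e-3 kcal/mol
        ff = quartic_double_well()
        sd = find_critical_point(ff, np.array([[0.1, 0, 0]]), "saddle1")
        p1 = trace_irc(ff, sd, step=0.01, max_images_per_branch=30)
        p2 = trace_irc(ff, sd, step=0.005, max_images_per_branch=60)
        lo = max(p1.arc.min(), p2.arc.min())
        hi = min(p1.arc.max(), p2.arc.max())
        grid = np.linspace(lo, hi, 50)
        e1 = np.interp(grid, p1.arc, p1.energies)
        e2 = np.interp(grid, p2.arc, p2.energies)
        assert np.abs(e1 - e2).max() < 1e-3

    def test_saddle_required(self, rtp):
        r = rtp.reactions[0]
        with pytest.raises(Exception, match="saddle"):
            trace_irc(r.ff, r.reactant)

    def test_ts_image_is_input_saddle(self, rtp):
        r = rtp.reactions[0]
        path = trace_irc(r.ff, r.ts, max_images_per_branch=10)
        assert np.allclose(path.images[path.ts_index].coordinates,
                           r.ts.coordinates)


class TestRTPDataset:
    def test_deterministic_given_seed(self, family, rtp):
        again = build_rtp_dataset(family, 6, seed=3)
        for a, b in zip(rtp.reactions, again.reactions):
            assert np.array_equal(a.ts.coordinates, b.ts.coordinates)
            assert a.ts.energy == b.ts.energy

    def test_ts_has_exactly_one_negative_eigenvalue(self, rtp):
        for r in rtp.reactions:
            assert hessian_index(r.ff, r.ts.coordinates) == 1
            assert hessian_index(r.ff, r.reactant.coordinates) == 0

    def test_endpoint_energies_below_ts(self, rtp):
        for r in rtp.reactions:
            e_ts = eval_reference(r.ff, r.ts.coordinates)[0]
            assert eval_reference(r.ff, r.reactant.coordinates)[0] <= e_ts
            assert eval_reference(r.ff, r.product.coordinates)[0] <= e_ts

    def test_label_fd_consistency_on_generated_structures(self, rtp):
        r = rtp.reactions[0]
        s = r.ts
        step = 1e-5
        for (a, d) in [(0, 0), (1, 1), (2, 2)]:
            xp, xm = s.coordinates.copy(), s.coordinates.copy()
            xp[a, d] += step
            xm[a, d] -= step
            fd = (r.ff.evaluate(xp, 0)[0] - r.ff.evaluate(xm, 0)[0]) / (2 * step)
            assert abs(-fd - s.forces[a, d]) < 1e-6 * max(1.0, abs(fd))
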