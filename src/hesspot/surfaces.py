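"""Analytic reference potential-energy surfaces with exact labels.

Three surface families cover the evaluation axes of the package:

* **Morse bond networks** — 3-D molecules built from pairwise Morse bonds
  plus bending terms expressed in q = cos(theta).  A *double-well* bending
  term gives each molecule two conformational minima joined by a single
  first-order saddle, which is the synthetic analog of an elementary
  reaction (reactant / transition state / product).
* **1-D quartic double well** — V(x) = c (x^4 - 2 x^2), minima at x = +-1
  with V = -c and an exact barrier of c; harmonic confinement in y, z.
* **Mueller-Brown** — the classic two-saddle 2-D surface, harmonically
  confined in z.

Energies are kcal/mol, lengths angstrom.  Gradients and Hessians are exact
chain-rule values obtained by propagating second-order jets through the
closed-form terms; they therefore agree with finite differences of the
energy to the accuracy of the difference scheme itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._scatter import hess_accumulator, hess_from_blocks, scatter_pair, scatter_triple
from .jets import Jet
from .structures import LabeledStructure, masses_for

logger = logging.getLogger(__name__)


class SurfaceError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Optimization did not converge; carries the final gradient norm."""

    def __init__(self, msg: str, grad_norm: float):
        super().__init__(f"{msg} (final max |grad| = {grad_norm:.3g})")
        self.grad_norm = grad_norm


class SaddleIndexError(RuntimeError):
    """Converged to a stationary point with the wrong Hessian index."""


# ---------------------------------------------------------------------------
# force-field terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseBond:
    i: int
    j: int
    depth: float        # D, kcal/mol
    width: float        # a, 1/angstrom
    r0: float           # angstrom

    def energy_jet(self, r: Jet) -> Jet:
        e = ((-self.width) * (r - self.r0)).exp()
        return self.depth * (1.0 - e) ** 2


@dataclass(frozen=True)
class HarmonicBend:
    """k_q (q - q0)^2 with q = cos(theta) at the center atom."""

    i: int
    center: int
    j: int
    k_q: float
    q0: float

    def energy_jet(self, r1: Jet, r2: Jet, q: Jet) -> Jet:
        return self.k_q * (q - self.q0) ** 2


@dataclass(frozen=True)
class StretchBendCoupling:
    """g [(r1 - r01) + (r2 - r02)] (q - q_ref): shifts equilibrium bond
    lengths as the bend angle changes, the way real conformers do."""

    i: int
    center: int
    j: int
    g: float            # kcal/(mol A)
    r01: float
    r02: float
    q_ref: float

    def energy_jet(self, r1: Jet, r2: Jet, q: Jet) -> Jet:
        return ((r1 - self.r01) + (r2 - self.r02)) * (q - self.q_ref) * self.g


@dataclass(frozen=True)
class DoubleWellBend:
    """Quartic double well in q = cos(theta), optionally tilted.

    V(q) = h [((q - m)/w)^2 - 1]^2 + s (q - m)/w.

    Wells sit near q = m -+ w with a barrier of h at q ~ m; the tilt s
    (|s| << h) breaks the reactant/product degeneracy.
    """

    i: int
    center: int
    j: int
    barrier: float      # h, kcal/mol
    q_mid: float        # m
    q_half_width: float # w
    tilt: float = 0.0   # s, kcal/mol

    def energy_jet(self, r1: Jet, r2: Jet, q: Jet) -> Jet:
        z = (q - self.q_mid) * (1.0 / self.q_half_width)
        return self.barrier * (z * z - 1.0) ** 2 + self.tilt * z


# ---------------------------------------------------------------------------
# reference force fields
# ---------------------------------------------------------------------------

@dataclass
class ReferenceFF:
    """Analytic force field: closed-form energy, gradient, Hessian."""

    kind: str
    species: tuple[str, ...]
    bonds: tuple[MorseBond, ...] = ()
    bends: tuple = ()
    params: dict = field(default_factory=dict)
    translation_invariant: bool = True

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        return masses_for(self.species)

    @property
    def bonded_pairs(self) -> list[tuple[int, int]]:
        return [(b.i, b.j) for b in self.bonds]

    def energy_and_forces(self, structure) -> tuple[float, np.ndarray]:
        """Calculator interface shared with trained potentials."""
        coords = structure.coordinates if hasattr(structure, "coordinates") else structure
        e, g, _ = self.evaluate(coords, order=1)
        return e, -g

    # -- evaluation ----------------------------------------------------
    def evaluate(self, coords: np.ndarray, order: int = 2):
        """Return (energy, gradient, hessian); higher orders None if not asked."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = self.n_atoms
        if coords.shape[0] != n:
            raise SurfaceError(
                f"structure has {coords.shape[0]} atoms, force field expects {n}"
            )
        if self.kind in ("quartic_double_well_1d", "mueller_brown_2d"):
            return self._evaluate_external(coords, order)
        return self._evaluate_network(coords, order)

    def _evaluate_network(self, coords: np.ndarray, order: int):
        n = self.n_atoms
        energy = 0.0
        grad = np.zeros((n, 3)) if order >= 1 else None
        hacc = hess_accumulator(n) if order >= 2 else None

        if self.bonds:
            I = np.array([b.i for b in self.bonds])
            J = np.array([b.j for b in self.bonds])
            u_val = coords[J] - coords[I]                      # (P, 3)
            seeds = np.broadcast_to(np.eye(3), (len(self.bonds), 3, 3))
            u = Jet.variable(u_val, seeds.copy(), order=order)
            r = (u * u).sum(axis=-1).sqrt()
            for p, bond in enumerate(self.bonds):
                rp = _slice_jet(r, p)
                e = bond.energy_jet(rp)
                energy += float(e.v)
                scatter_pair(n, I[p:p + 1], J[p:p + 1],
                             None if e.g is None else e.g[None],
                             None if e.h is None else e.h[None],
                             grad, hacc)

        for bend in self.bends:
            i, c, k = bend.i, bend.center, bend.j
            uv_val = np.concatenate([coords[i] - coords[c], coords[k] - coords[c]])
            uv = Jet.variable(uv_val, np.eye(6), order=order)
            u = _slice_vec(uv, 0)
            v = _slice_vec(uv, 1)
            r1 = (u * u).sum(axis=-1).sqrt()
            r2 = (v * v).sum(axis=-1).sqrt()
            q = (u * v).sum(axis=-1) / (r1 * r2)
            e = bend.energy_jet(r1, r2, q)
            energy += float(e.v)
            scatter_triple(n, np.array([i]), np.array([c]), np.array([k]),
                           None if e.g is None else e.g[None],
                           None if e.h is None else e.h[None],
                           grad, hacc)

        hess = hess_from_blocks(hacc, n) if order >= 2 else None
        if hess is not None:
            hess = 0.5 * (hess + hess.T)   # remove round-off asymmetry
        return energy, grad, hess

    def _evaluate_external(self, coords: np.ndarray, order: int):
        x = Jet.variable(coords[0], np.eye(3), order=order)
        xc, yc, zc = _slice_comp(x, 0), _slice_comp(x, 1), _slice_comp(x, 2)
        if self.kind == "quartic_double_well_1d":
            c = self.params["scale"]
            kp = self.params["k_perp"]
            e = c * (xc ** 4 - 2.0 * (xc ** 2)) + 0.5 * kp * (yc ** 2 + zc ** 2)
        else:  # mueller_brown_2d
            A = self.params["A"]
            a = self.params["a"]
            b = self.params["b"]
            cc = self.params["c"]
            x0 = self.params["x0"]
            y0 = self.params["y0"]
            kz = self.params["k_z"]
            e = 0.5 * kz * (zc ** 2)
            for t in range(4):
                dx = xc - x0[t]
                dy = yc - y0[t]
                e = e + A[t] * (a[t] * dx * dx + b[t] * dx * dy + cc[t] * dy * dy).exp()
        energy = float(e.v)
        grad = None if order < 1 else e.g.reshape(1, 3)
        hess = None if order < 2 else 0.5 * (e.h + e.h.T)
        return energy, grad, hess


def _slice_jet(j: Jet, p: int) -> Jet:
    return Jet(j.v[p], None if j.g is None else j.g[p],
               None if j.h is None else j.h[p])


def _slice_vec(uv: Jet, which: int) -> Jet:
    s = slice(3 * which, 3 * which + 3)
    return Jet(uv.v[s], None if uv.g is None else uv.g[s],
               None if uv.h is None else uv.h[s])


def _slice_comp(x: Jet, c: int) -> Jet:
    return Jet(x.v[c], None if x.g is None else x.g[c],
               None if x.h is None else x.h[c])


# ---------------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------------

def morse_diatomic(depth: float = 1.0, width: float = 1.0, r0: float = 1.0,
                   species: tuple[str, str] = ("H", "H")) -> ReferenceFF:
    return ReferenceFF("morse_bond_network", tuple(species),
                       bonds=(MorseBond(0, 1, depth, width, r0),),
                       params={"depth": depth, "width": width, "r0": r0})


def morse_network(species: Sequence[str], bonds: Sequence[MorseBond],
                  bends: Sequence = ()) -> ReferenceFF:
    return ReferenceFF("morse_bond_network", tuple(species),
                       bonds=tuple(bonds), bends=tuple(bends))


def quartic_double_well(scale: float = 1.0, k_perp: float = 5.0,
                        species: tuple[str, ...] = ("H",)) -> ReferenceFF:
    """V = scale (x^4 - 2 x^2): minima (+-1, V=-scale), saddle (0, V=0)."""
    return ReferenceFF("quartic_double_well_1d", tuple(species),
                       params={"scale": scale, "k_perp": k_perp},
                       translation_invariant=False)


def mueller_brown(k_z: float = 200.0, species: tuple[str, ...] = ("H",)) -> ReferenceFF:
    """Mueller-Brown surface in (x, y), stiff harmonic confinement in z."""
    return ReferenceFF(
        "mueller_brown_2d", tuple(species),
        params={
            "A": (-200.0, -100.0, -170.0, 15.0),
            "a": (-1.0, -1.0, -6.5, 0.7),
            "b": (0.0, 0.0, 11.0, 0.6),
            "c": (-10.0, -10.0, -6.5, 0.7),
            "x0": (1.0, 0.0, -0.5, -1.0),
            "y0": (0.0, 0.5, 1.5, 1.0),
            "k_z": k_z,
        },
        translation_invariant=False,
    )


def eval_reference(ff: ReferenceFF, structure) -> tuple[float, np.ndarray, np.ndarray]:
    """Closed-form (energy, forces, hessian) for a structure on ``ff``.

    Forces are the negative gradient; the Hessian is symmetric.
    Accepts a LabeledStructure or a coordinate array.
    """
    coords = structure.coordinates if hasattr(structure, "coordinates") else structure
    e, g, h = ff.evaluate(coords, order=2)
    return e, -g, h


def label_structure(ff: ReferenceFF, coords: np.ndarray,
                    info: Optional[dict] = None) -> LabeledStructure:
    e, f, h = eval_reference(ff, coords)
    return LabeledStructure(ff.species, np.array(coords, dtype=float),
                            energy=e, forces=f, hessian=h, info=info or {})


# ---------------------------------------------------------------------------
# critical-point search (Newton with eigenvector following)
# ---------------------------------------------------------------------------

def _trans_rot_basis(coords: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of rigid translations and rotations, (3n, k)."""
    vecs = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        vecs.append(t.ravel())
    center = coords.mean(axis=0)
    rel = coords - center
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, rel.shape), rel)
        vecs.append(r.ravel())
    B = np.stack(vecs, axis=1)
    # orthonormalize, dropping near-null columns (linear molecules)
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def hessian_index(ff: ReferenceFF, coords: np.ndarray,
                  neg_tol: float = 1e-3) -> int:
    """Number of negative Hessian eigenvalues after removing the
    translational/rotational null space (if the surface has one)."""
    _, _, H = ff.evaluate(coords, order=2)
    n = ff.n_atoms
    if ff.translation_invariant:
        B = _trans_rot_basis(coords.reshape(-1, 3), n)
        P = np.eye(3 * n) - B @ B.T
        H = P @ H @ P + 1e6 * (B @ B.T)   # push null modes far positive
    lam = np.linalg.eigvalsh(H)
    return int((lam < -neg_tol).sum())


def find_critical_point(ff: ReferenceFF, x0: np.ndarray, kind: str = "minimum",
                        gtol: float = 1e-3, trust: float = 0.1,
                        maxiter: int = 500) -> LabeledStructure:
    """Locate a stationary point of the requested Hessian index.

    kind: "minimum" (index 0) or "saddle1" (index 1).  Default gradient
    tolerance 1e-3 kcal/(mol A) on the max component — much tighter than
    typical electronic-structure criteria, affordable because labels are
    analytic.  Raises :class:`ConvergenceError` / :class:`SaddleIndexError`.
    """
    if kind not in ("minimum", "saddle1"):
        raise ValueError(f"unknown kind {kind!r}")
    target_index = 0 if kind == "minimum" else 1
    n = ff.n_atoms
    x = np.array(x0, dtype=float).reshape(n, 3)
    floor = 1e-2
    gmax = np.inf
    for _ in range(maxiter):
        _, g, H = ff.evaluate(x, order=2)
        gflat = g.ravel()
        if ff.translation_invariant:
            B = _trans_rot_basis(x, n)
            P = np.eye(3 * n) - B @ B.T
            gflat = P @ gflat
            H = P @ H @ P
        gmax = np.abs(gflat).max()
        if gmax < gtol:
            idx = hessian_index(ff, x)
            if idx != target_index:
                raise SaddleIndexError(
                    f"converged to stationary point with Hessian index {idx}, "
                    f"wanted {target_index}"
                )
            return label_structure(ff, x, info={"kind": kind, "gmax": float(gmax)})
        lam, vecs = np.linalg.eigh(H)
        null = np.zeros(3 * n, dtype=bool)
        if ff.translation_invariant:
            ov = np.linalg.norm(B.T @ vecs, axis=0)
            null = ov > 0.5
        live = ~null
        lam_mod = lam.copy()
        if kind == "minimum":
            lam_mod[live] = np.maximum(lam[live], floor)
        else:
            live_idx = np.nonzero(live)[0]
            lowest = live_idx[np.argmin(lam[live_idx])]
            lam_mod[live] = np.maximum(lam[live], floor)
            lam_mod[lowest] = min(lam[lowest], -floor)
        gmode = vecs.T @ gflat
        step_modes = np.where(live, -gmode / lam_mod, 0.0)
        step = vecs @ step_modes
        norm = np.linalg.norm(step)
        if norm > trust * math.sqrt(n):
            step *= trust * math.sqrt(n) / norm
        x = x + step.reshape(n, 3)
    raise ConvergenceError("critical-point search did not converge", gmax)


# ---------------------------------------------------------------------------
# IRC tracing
# ---------------------------------------------------------------------------

@dataclass
class IRCPath:
    """Mass-weighted steepest-descent path through a first-order saddle.

    ``arc`` is the mass-weighted arc length (amu^1/2 angstrom), zero at
    the transition state, negative toward the reactant branch.
    ``tangents`` are unit path tangents in mass-weighted coordinates,
    oriented along increasing arc.
    """

    images: list[LabeledStructure]
    arc: np.ndarray
    ts_index: int
    tangents: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def energies(self) -> np.ndarray:
        return np.array([im.energy for im in self.images])


def trace_irc(ff: ReferenceFF, saddle: LabeledStructure, step: float = 0.01,
              max_steps: int = 50000, end_gtol: float = 5e-3,
              end_gtol_rel: float = 0.02,
              max_images_per_branch: int = 40) -> IRCPath:
    """Trace both steepest-descent branches from a first-order saddle.

    Fixed-step Euler integration in mass-weighted coordinates (step in
    amu^1/2 angstrom), seeded +-step along the negative-curvature
    eigenvector; each branch is terminated by a local minimization once
    the mass-weighted gradient falls below ``end_gtol`` or below
    ``end_gtol_rel`` times the largest gradient met along the branch
    (so walks do not stop in the small-gradient region next to the
    saddle, yet terminate cleanly in stiff terminal basins).
    """
    coords0 = saddle.coordinates
    if hessian_index(ff, coords0) != 1:
        raise SurfaceError("trace_irc requires a Hessian-index-1 saddle")
    masses = ff.masses
    sqm = np.repeat(np.sqrt(masses), 3)
    _, _, H = ff.evaluate(coords0, order=2)
    Hmw = H / np.outer(sqm, sqm)
    lam, vecs = np.linalg.eigh(Hmw)
    mode = vecs[:, np.argmin(lam)]

    def grad_mw(y):
        e, g, _ = ff.evaluate((y / sqm).reshape(-1, 3), order=1)
        return e, g.ravel() / sqm

    def run_branch(sign):
        y = coords0.ravel() * sqm + sign * step * mode
        pts = []          # (arc_from_ts, y, energy)
        arc = step
        e, g = grad_mw(y)
        pts.append((arc, y.copy(), e))
        local = step
        g_max = 0.0
        for _ in range(max_steps):
            gnorm = np.linalg.norm(g)
            g_max = max(g_max, gnorm)
            if gnorm < max(end_gtol, end_gtol_rel * g_max):
                break
            y_new = y - local * g / gnorm
            e_new, g_new = grad_mw(y_new)
            if e_new > e + 1e-12:
                # descent blocked at this resolution: stiff transverse modes
                # dominate and the walk has entered the terminal basin
                local *= 0.5
                if local < step * 1e-3:
                    break
                continue
            if e - e_new < 1e-10:
                break
            arc += np.linalg.norm(y_new - y)
            y, e, g = y_new, e_new, g_new
            local = min(step, local * 1.3)
            pts.append((arc, y.copy(), e))
        else:
            raise ConvergenceError("IRC branch failed to reach a minimum",
                                   float(np.linalg.norm(g)))
        # polish the endpoint to the exact minimum
        end = find_critical_point(ff, (y / sqm).reshape(-1, 3), "minimum",
                                  gtol=1e-5)
        y_end = end.coordinates.ravel() * sqm
        d = np.linalg.norm(y_end - y)
        if d > 1e-10:
            arc += d
            pts.append((arc, y_end, end.energy))
        # subsample to a bounded number of images
        if len(pts) > max_images_per_branch:
            idx = np.unique(np.linspace(0, len(pts) - 1,
                                        max_images_per_branch).astype(int))
            pts = [pts[i] for i in idx]
        return pts

    neg_branch = run_branch(-1.0)
    pos_branch = run_branch(+1.0)

    images, arcs, tangents = [], [], []
    # reactant side: negative arc, ordered from the far minimum toward TS
    for arc, y, _e in reversed(neg_branch):
        images.append(label_structure(ff, (y / sqm).reshape(-1, 3)))
        arcs.append(-arc)
    images.append(label_structure(ff, coords0))
    arcs.append(0.0)
    ts_index = len(images) - 1
    for arc, y, _e in pos_branch:
        images.append(label_structure(ff, (y / sqm).reshape(-1, 3)))
        arcs.append(arc)

    arcs = np.array(arcs)
    ys = np.stack([im.coordinates.ravel() * sqm for im in images])
    for k in range(len(images)):
        if k == ts_index:
            t = mode.copy()
        elif k == 0:
            t = ys[1] - ys[0]
        elif k == len(images) - 1:
            t = ys[-1] - ys[-2]
        else:
            t = ys[k + 1] - ys[k - 1]
        t = t / np.linalg.norm(t)
        tangents.append(t)
        images[k].info["arc"] = float(arcs[k])
        images[k].info["tangent_mw"] = t

    return IRCPath(images, arcs, ts_index, tangents)


# ---------------------------------------------------------------------------
# reaction family / RTP dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriatomicFamily:
    """Family of bent triatomics whose "reaction" is a bend-angle flip.

    Every molecule is terminal-center-terminal with two Morse bonds and a
    tilted double-well bending term, so each surface has exactly two
    conformational minima joined by one first-order saddle.  Crucially,
    all force-field parameters are a *fixed deterministic function of the
    element combination* (drawn once from ``universe_seed``): the family
    defines a single consistent potential-energy surface over compositions,
    the way one level of electronic-structure theory does, and reaction
    diversity comes from sampling distinct compositions.  Ranges are the
    study conditions; energies kcal/mol, lengths angstrom.
    """

    elements: tuple[str, ...] = ("H", "C", "N", "O", "S")
    universe_seed: int = 20240901
    depth_range: tuple[float, float] = (60.0, 120.0)
    width_range: tuple[float, float] = (1.6, 2.4)
    r0_range: tuple[float, float] = (0.96, 1.45)
    theta1_range_deg: tuple[float, float] = (85.0, 110.0)
    theta2_range_deg: tuple[float, float] = (135.0, 160.0)
    barrier_range: tuple[float, float] = (3.0, 8.0)
    tilt_frac_range: tuple[float, float] = (-0.2, 0.2)
    coupling_range: tuple[float, float] = (20.0, 60.0)   # |g|, kcal/(mol A)

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.universe_seed, *key]))

    def bond_params(self, center: str, terminal: str) -> MorseBond:
        ci = self.elements.index(center)
        ti = self.elements.index(terminal)
        rng = self._rng(1, ci, ti)
        return MorseBond(1, -1,   # atom indices filled in by reaction_ff
                         depth=rng.uniform(*self.depth_range),
                         width=rng.uniform(*self.width_range),
                         r0=rng.uniform(*self.r0_range))

    def bend_params(self, center: str, t1: str, t2: str) -> dict:
        ci = self.elements.index(center)
        a, b = sorted((self.elements.index(t1), self.elements.index(t2)))
        rng = self._rng(2, ci, a, b)
        th1 = math.radians(rng.uniform(*self.theta1_range_deg))
        th2 = math.radians(rng.uniform(*self.theta2_range_deg))
        h = rng.uniform(*self.barrier_range)
        s = h * rng.uniform(*self.tilt_frac_range)
        g = rng.uniform(*self.coupling_range) * rng.choice([-1.0, 1.0])
        return {"theta": (th1, th2), "barrier": h, "tilt": s, "coupling": g}

    def compositions(self) -> list[tuple[str, str, str]]:
        """All (terminal, center, terminal) combos, terminals unordered."""
        out = []
        for c in self.elements:
            for i, t1 in enumerate(self.elements):
                for t2 in self.elements[i:]:
                    out.append((t1, c, t2))
        return out

    def reaction_ff(self, composition: tuple[str, str, str]
                    ) -> tuple[ReferenceFF, dict]:
        t1, center, t2 = composition
        b1 = self.bond_params(center, t1)
        b2 = self.bond_params(center, t2)
        bonds = (MorseBond(1, 0, b1.depth, b1.width, b1.r0),
                 MorseBond(1, 2, b2.depth, b2.width, b2.r0))
        bp = self.bend_params(center, t1, t2)
        th1, th2 = bp["theta"]
        q1, q2 = math.cos(th1), math.cos(th2)
        bend = DoubleWellBend(i=0, center=1, j=2, barrier=bp["barrier"],
                              q_mid=0.5 * (q1 + q2),
                              q_half_width=0.5 * abs(q1 - q2),
                              tilt=bp["tilt"])
        couple = StretchBendCoupling(i=0, center=1, j=2, g=bp["coupling"],
                                     r01=b1.r0, r02=b2.r0,
                                     q_ref=0.5 * (q1 + q2))
        ff = ReferenceFF("morse_bond_network", (t1, center, t2),
                         bonds=bonds, bends=(bend, couple))
        params = {
            "species": list(composition),
            "r0": [b.r0 for b in bonds],
            "depth": [b.depth for b in bonds],
            "width": [b.width for b in bonds],
            "theta_deg": [math.degrees(th1), math.degrees(th2)],
            "barrier": bp["barrier"],
            "tilt": bp["tilt"],
        }
        return ff, params


def _bent_geometry(r1: float, r2: float, theta: float) -> np.ndarray:
    """Terminal-center-terminal geometry with bend angle theta at the center."""
    return np.array([
        [r1, 0.0, 0.0],
        [0.0, 0.0, 0.0],
        [r2 * math.cos(theta), r2 * math.sin(theta), 0.0],
    ])


@dataclass
class Reaction:
    reactant: LabeledStructure
    ts: LabeledStructure
    product: LabeledStructure
    ff: ReferenceFF
    params: dict

    @property
    def structures(self) -> list[LabeledStructure]:
        return [self.reactant, self.ts, self.product]


@dataclass
class RTPDataset:
    """Reactant/transition-state/product triples with exact labels."""

    reactions: list[Reaction]
    provenance: dict

    @property
    def structures(self) -> list[LabeledStructure]:
        out = []
        for r in self.reactions:
            out.extend(r.structures)
        return out

    def __len__(self) -> int:
        return len(self.reactions)


def build_rtp_dataset(family: TriatomicFamily, n_reactions: int, seed: int,
                      min_success_fraction: float = 0.8) -> RTPDataset:
    """Draw a deterministic family of reactions and label their critical points.

    Failed critical-point searches skip the reaction with a logged warning;
    an error is raised if fewer than ``min_success_fraction`` of the
    requested reactions succeed.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    combos = family.compositions()
    if n_reactions > len(combos):
        raise ValueError(
            f"family supports at most {len(combos)} distinct reactions")
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 0x52545044]))
    picked = [combos[i] for i in root.permutation(len(combos))[:n_reactions]]
    reactions = []
    attempts = []
    for k, combo in enumerate(picked):
        ff, params = family.reaction_ff(combo)
        th1, th2 = (math.radians(t) for t in params["theta_deg"])
        th_mid = math.acos(0.5 * (math.cos(th1) + math.cos(th2)))
        r1, r2 = params["r0"]
        try:
            # tight gradient tolerance keeps rigid-body Hessian eigenvalues
            # (hence spurious near-zero frequencies) at the 0.1 cm^-1 level
            reactant = find_critical_point(ff, _bent_geometry(r1, r2, th1),
                                           "minimum", gtol=1e-6)
            product = find_critical_point(ff, _bent_geometry(r1, r2, th2),
                                          "minimum", gtol=1e-6)
            ts = find_critical_point(ff, _bent_geometry(r1, r2, th_mid),
                                     "saddle1", gtol=1e-6)
        except (ConvergenceError, SaddleIndexError) as exc:
            logger.warning("reaction %d skipped: %s", k, exc)
            attempts.append({"index": k, "params": params, "error": str(exc)})
            continue
        if ts.energy < max(reactant.energy, product.energy):
            logger.warning("reaction %d skipped: TS below an endpoint", k)
            continue
        reactions.append(Reaction(reactant, ts, product, ff, params))
    if len(reactions) < min_success_fraction * n_reactions:
        raise SurfaceError(
            f"only {len(reactions)}/{n_reactions} reactions converged"
        )
    return RTPDataset(reactions, {"seed": int(seed),
                                  "n_requested": n_reactions,
                                  "family": family.__dict__.copy(),
                                  "failures": attempts})
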