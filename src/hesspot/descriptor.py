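"""Atomic environment vectors (modified Behler-Parrinello symmetry functions).

Each atom's environment is encoded as a fixed-length vector of radial and
angular probes in the style of the ANI descriptor family:

    radial   G_r(i; X, Rs)        = sum_{j in X} exp(-eta_r (r_ij - Rs)^2) f_c(r_ij)
    angular  G_a(i; {X,Y}, ts, Rs) = 2^(1-zeta) sum_{j<k, {Z_j,Z_k}={X,Y}}
                 (1 + cos(theta_ijk - ts))^zeta
                 * exp(-eta_a ((r_ij + r_ik)/2 - Rs)^2) f_c(r_ij) f_c(r_ik)

The default cutoff function is a polynomial (1 - (r/Rc)^2)^3 whose second
derivative vanishes at Rc, so the descriptor is C^2 and predicted Hessians
are continuous; the traditional cosine cutoff (curvature kink at Rc) is
retained as an option.  ``featurize_structure`` also returns exact first
and second derivatives of every descriptor entry with respect to all
Cartesian coordinates, which is what makes nested differentiation of the
learned energy possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .jets import Jet
from .structures import LabeledStructure, PaddedBatch


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class AEVSpec:
    """Hyperparameters of the atomic-environment-vector descriptor."""

    elements: tuple[str, ...] = ("H", "C", "O")
    cutoff: float = 4.6                           # Rc, angstrom
    radial_shifts: tuple[float, ...] = tuple(np.linspace(0.8, 4.2, 8))
    eta_radial: float = 8.0                       # 1/angstrom^2
    angular_theta_shifts: tuple[float, ...] = tuple(np.linspace(0.0, np.pi, 4))
    zeta: int = 8
    angular_radial_shifts: tuple[float, ...] = tuple(np.linspace(0.8, 2.9, 4))
    eta_angular: float = 4.0
    cutoff_fn: str = "smooth_poly"                # or "cosine"

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_pairs(self) -> list[tuple[int, int]]:
        ne = self.n_elements
        return [(a, b) for a in range(ne) for b in range(a, ne)]

    @property
    def n_radial(self) -> int:
        return len(self.radial_shifts)

    @property
    def n_angular(self) -> int:
        return len(self.angular_theta_shifts) * len(self.angular_radial_shifts)

    @property
    def length(self) -> int:
        return (self.n_elements * self.n_radial
                + len(self.element_pairs) * self.n_angular)

    def element_index(self, species) -> np.ndarray:
        try:
            return np.array([self.elements.index(s) for s in species])
        except ValueError:
            bad = [s for s in species if s not in self.elements]
            raise DescriptorError(f"element(s) {bad} not in alphabet "
                                  f"{self.elements}") from None

    def pair_channel_base(self) -> np.ndarray:
        """(ne, ne) -> base channel offset of the element-pair block."""
        ne = self.n_elements
        base = np.zeros((ne, ne), dtype=int)
        for p, (a, b) in enumerate(self.element_pairs):
            off = ne * self.n_radial + p * self.n_angular
            base[a, b] = off
            base[b, a] = off
        return base


@dataclass
class AEVBatch:
    """(M, N, L) descriptor grid with the batch's atom mask."""

    values: np.ndarray
    atom_mask: np.ndarray
    spec: AEVSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# cutoff function: value and first two derivatives in r
# ---------------------------------------------------------------------------

def _cutoff(r: np.ndarray, spec: AEVSpec):
    rc = spec.cutoff
    u = r / rc
    if spec.cutoff_fn == "smooth_poly":
        w = 1.0 - u * u
        f = w ** 3
        f1 = -6.0 * r / rc ** 2 * w ** 2
        f2 = -6.0 / rc ** 2 * w ** 2 + 24.0 * r ** 2 / rc ** 4 * w
    elif spec.cutoff_fn == "cosine":
        f = 0.5 * (np.cos(np.pi * u) + 1.0)
        f1 = -0.5 * np.pi / rc * np.sin(np.pi * u)
        f2 = -0.5 * (np.pi / rc) ** 2 * np.cos(np.pi * u)
    else:
        raise DescriptorError(f"unknown cutoff_fn {spec.cutoff_fn!r}")
    inside = r < rc
    return f * inside, f1 * inside, f2 * inside


def _fc_jet(r: Jet, spec: AEVSpec) -> Jet:
    f, f1, f2 = _cutoff(r.v, spec)
    return r._chain(f, f1, f2)


def _tile_jet(j: Jet, s: int) -> Jet:
    """Append a broadcast axis of size s to the value shape."""
    v = np.repeat(j.v[..., None], s, axis=-1)
    if j.order == 0:
        return Jet(v)
    g = np.repeat(j.g[..., None, :], s, axis=-2)
    if j.order == 1:
        return Jet(v, g)
    h = np.repeat(j.h[..., None, :, :], s, axis=-3)
    return Jet(v, g, h)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize_structure(structure: LabeledStructure, spec: AEVSpec,
                        order: int = 0,
                        pad_to: Optional[int] = None):
    """Descriptors and their coordinate derivatives for one molecule.

    Returns ``(G, dG, d2G)`` with shapes (n, L), (n, L, 3N), (n, L, 3N, 3N)
    where N = ``pad_to`` or n; entries beyond the molecule's own
    coordinates are zero.  ``dG``/``d2G`` are None below the requested
    derivative order.
    """
    coords = structure.coordinates
    n = coords.shape[0]
    N = n if pad_to is None else int(pad_to)
    if N < n:
        raise DescriptorError("pad_to smaller than atom count")
    L = spec.length
    elem = spec.element_index(structure.species)

    G = np.zeros((n, L))
    dG = np.zeros((n, L, 3 * N)) if order >= 1 else None
    # atom-block layout (n, L, N, N, 3, 3) so scatter targets are contiguous
    d2G_blk = np.zeros((n, L, N, N, 3, 3)) if order >= 2 else None

    if n >= 2:
        _radial_terms(coords, elem, spec, order, G, dG, d2G_blk, N)
    if n >= 3:
        _angular_terms(coords, elem, spec, order, G, dG, d2G_blk, N)
    d2G = None
    if order >= 2:
        d2G = (d2G_blk.transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, L, 3 * N, 3 * N))
    return G, dG, d2G


def _radial_terms(coords, elem, spec, order, G, dG, d2G, N):
    n = coords.shape[0]
    L = spec.length
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    ii, jj = np.nonzero((dist < spec.cutoff) & ~np.eye(n, dtype=bool))
    if len(ii) == 0:
        return
    I, J = ii, jj
    u_val = coords[J] - coords[I]
    seeds = np.broadcast_to(np.eye(3), (len(I), 3, 3)).copy()
    u = Jet.variable(u_val, seeds, order=order)
    r = (u * u).sum(axis=-1).sqrt()

    # per (pair, shift) scalar function of r
    S = spec.n_radial
    rv = r.v[:, None]
    Rs = np.asarray(spec.radial_shifts)[None, :]
    eta = spec.eta_radial
    E = np.exp(-eta * (rv - Rs) ** 2)
    E1 = -2.0 * eta * (rv - Rs) * E
    E2 = (4.0 * eta ** 2 * (rv - Rs) ** 2 - 2.0 * eta) * E
    f, f1, f2 = _cutoff(r.v, spec)
    f, f1, f2 = f[:, None], f1[:, None], f2[:, None]
    T = E * f
    T1 = E1 * f + E * f1
    T2 = E2 * f + 2.0 * E1 * f1 + E * f2

    ch = elem[J][:, None] * S + np.arange(S)[None, :]        # (P, S)
    np.add.at(G.ravel(), I[:, None] * L + ch, T)
    if order >= 1:
        g = T1[..., None] * r.g[:, None, :]                  # (P, S, 3)
        flat = dG.reshape(-1, 3)
        base = (I[:, None] * L + ch) * N
        np.add.at(flat, base + J[:, None], g)
        np.add.at(flat, base + I[:, None], -g)
    if order >= 2:
        outer = r.g[:, :, None] * r.g[:, None, :]
        h = (T1[..., None, None] * r.h[:, None, :, :]
             + T2[..., None, None] * outer[:, None, :, :])   # (P, S, 3, 3)
        flat = d2G.reshape(-1, 3, 3)
        base = ((I[:, None] * L + ch) * N)
        np.add.at(flat, (base + J[:, None]) * N + J[:, None], h)
        np.add.at(flat, (base + I[:, None]) * N + I[:, None], h)
        np.add.at(flat, (base + I[:, None]) * N + J[:, None], -h)
        np.add.at(flat, (base + J[:, None]) * N + I[:, None],
                  -np.swapaxes(h, -1, -2))


def _angular_terms(coords, elem, spec, order, G, dG, d2G, N):
    n = coords.shape[0]
    L = spec.length
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    within = (dist < spec.cutoff) & ~np.eye(n, dtype=bool)
    C_list, J_list, K_list = [], [], []
    for c in range(n):
        nb = np.nonzero(within[c])[0]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                C_list.append(c)
                J_list.append(nb[a])
                K_list.append(nb[b])
    if not C_list:
        return
    C = np.array(C_list)
    J = np.array(J_list)
    K = np.array(K_list)
    T_n = len(C)

    uv_val = np.concatenate([coords[J] - coords[C], coords[K] - coords[C]], axis=1)
    seeds = np.broadcast_to(np.eye(6), (T_n, 6, 6)).copy()
    uv = Jet.variable(uv_val, seeds, order=order)
    u = Jet(uv.v[:, :3], None if uv.g is None else uv.g[:, :3],
            None if uv.h is None else uv.h[:, :3])
    v = Jet(uv.v[:, 3:], None if uv.g is None else uv.g[:, 3:],
            None if uv.h is None else uv.h[:, 3:])
    r1 = (u * u).sum(axis=-1).sqrt()
    r2 = (v * v).sum(axis=-1).sqrt()
    q = (u * v).sum(axis=-1) / (r1 * r2)
    theta = q.arccos()
    fc1 = _fc_jet(r1, spec)
    fc2 = _fc_jet(r2, spec)
    rmean = (r1 + r2) * 0.5
    envelope = fc1 * fc2                                      # (T,)

    n_ts = len(spec.angular_theta_shifts)
    n_rs = len(spec.angular_radial_shifts)
    S = n_ts * n_rs
    ts_grid = np.repeat(np.asarray(spec.angular_theta_shifts), n_rs)
    rs_grid = np.tile(np.asarray(spec.angular_radial_shifts), n_ts)

    theta_t = _tile_jet(theta, S)
    rmean_t = _tile_jet(rmean, S)
    env_t = _tile_jet(envelope, S)
    ang = (1.0 + (theta_t - ts_grid).cos()) ** int(spec.zeta)
    rad = (((rmean_t - rs_grid) ** 2) * (-spec.eta_angular)).exp()
    term = 2.0 ** (1 - spec.zeta) * ang * rad * env_t         # (T, S) jets over 6 dirs

    pair_base = spec.pair_channel_base()
    ch = pair_base[elem[J], elem[K]][:, None] + np.arange(S)[None, :]
    np.add.at(G.ravel(), C[:, None] * L + ch, term.v)
    if order >= 1:
        g = term.g                                            # (T, S, 6)
        gu, gv = g[..., :3], g[..., 3:]
        flat = dG.reshape(-1, 3)
        base = (C[:, None] * L + ch) * N
        np.add.at(flat, base + J[:, None], gu)
        np.add.at(flat, base + K[:, None], gv)
        np.add.at(flat, base + C[:, None], -(gu + gv))
    if order >= 2:
        h = term.h                                            # (T, S, 6, 6)
        huu = h[..., :3, :3]
        huv = h[..., :3, 3:]
        hvu = h[..., 3:, :3]
        hvv = h[..., 3:, 3:]
        flat = d2G.reshape(-1, 3, 3)
        base = (C[:, None] * L + ch) * N

        def put(a, b, blk):
            np.add.at(flat, (base + a[:, None]) * N + b[:, None], blk)

        put(J, J, huu)
        put(K, K, hvv)
        put(J, K, huv)
        put(K, J, hvu)
        put(C, C, huu + huv + hvu + hvv)
        put(J, C, -(huu + huv))
        put(C, J, -(huu + hvu))
        put(K, C, -(hvu + hvv))
        put(C, K, -(huv + hvv))


def compute_aev(batch: PaddedBatch, spec: AEVSpec) -> AEVBatch:
    """Descriptor values for every atom of a padded batch; padded rows zero."""
    M, N = batch.n_molecules, batch.max_atoms
    values = np.zeros((M, N, spec.length))
    for m in range(M):
        nm = int(batch.atom_mask[m].sum())
        s = LabeledStructure(batch.species[m][:nm], batch.coordinates[m, :nm])
        G, _, _ = featurize_structure(s, spec, order=0)
        values[m, :nm] = G
    return AEVBatch(values, batch.atom_mask.copy(), spec)
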