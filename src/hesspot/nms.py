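"""Normal-mode sampling of perturbed off-path structures.

Given a structure and its Hessian, draw random displacements along the
mass-weighted normal modes, excluding a designated reaction-coordinate
mode (the IRC path tangent off the transition state, or the
negative-curvature eigenvector at it).  Per included mode i with
mass-weighted force constant k_i the coefficient is

    c_i = +- sqrt(3 k_B T R / k_i),   R ~ Uniform(0, 1), random sign,

so each mode receives on average 3 k_B T / 4 of potential energy — the
normal-mode-sampling rule of the ANI data-generation lineage.  Modes with
k_i below a stiffness floor (translations/rotations, and any imaginary
mode) are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .constants import KB_KCALMOL
from .structures import LabeledStructure
from .vibrations import mass_weighted_hessian


class NMSError(ValueError):
    pass


def _trans_rot_basis_mw(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted rigid translation/rotation basis, (3n, k)."""
    n = coords.shape[0]
    sqm = np.sqrt(masses)
    vecs = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        vecs.append((t * sqm[:, None]).ravel())
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    rel = coords - com
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, rel.shape), rel)
        vecs.append((r * sqm[:, None]).ravel())
    B = np.stack(vecs, axis=1)
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


@dataclass
class NMSConfig:
    """Sampling conditions; temperature in K, displacements in angstrom."""

    temperature: float = 300.0
    n_samples: int = 10
    seed: int = 0
    excluded_mode: Optional[Union[int, np.ndarray]] = None
    max_displacement: float = 0.5          # per-atom safety clip
    stiffness_floor: float = 1e-3          # kcal/(mol A^2 amu)
    exclude_trans_rot: bool = True         # project out rigid-body modes

    def __post_init__(self):
        if self.temperature <= 0:
            raise NMSError("temperature must be positive")


def sample_nms(structure: LabeledStructure, hessian: np.ndarray,
               masses: np.ndarray, config: NMSConfig) -> list[LabeledStructure]:
    """Draw perturbed copies of ``structure`` (coordinates only, no labels)."""
    n = structure.n_atoms
    masses = np.asarray(masses, dtype=float)
    lam, vecs = np.linalg.eigh(mass_weighted_hessian(hessian, masses))

    excl_vec = None
    if config.excluded_mode is not None:
        if isinstance(config.excluded_mode, (int, np.integer)):
            idx = int(config.excluded_mode)
            if not 0 <= idx < 3 * n:
                raise NMSError(f"mode index {idx} out of range for 3N = {3*n}")
            excl_vec = vecs[:, np.argsort(lam)][:, idx]
        else:
            excl_vec = np.asarray(config.excluded_mode, dtype=float).ravel()
            if excl_vec.shape != (3 * n,):
                raise NMSError("excluded_mode vector must have length 3N")
            nrm = np.linalg.norm(excl_vec)
            if nrm < 1e-12:
                raise NMSError("excluded_mode vector is zero")
            excl_vec = excl_vec / nrm

    include = lam > config.stiffness_floor
    if config.exclude_trans_rot:
        # rigid-body modes at non-stationary geometries carry small but
        # nonzero eigenvalues; sampling them as soft vibrations would draw
        # huge unphysical displacements, so they are excluded by overlap
        # with the mass-weighted translation/rotation subspace.
        B = _trans_rot_basis_mw(structure.coordinates, masses)
        include &= np.linalg.norm(B.T @ vecs, axis=0) < 0.5
    if excl_vec is not None:
        overlap = np.abs(vecs.T @ excl_vec)
        include &= overlap < 0.9          # drop the mode(s) aligned with it

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), 0x4e4d53]))
    sqm = np.repeat(np.sqrt(masses), 3)
    kT3 = 3.0 * KB_KCALMOL * config.temperature
    out = []
    for _ in range(config.n_samples):
        R = rng.uniform(0.0, 1.0, size=lam.shape)
        sign = rng.choice([-1.0, 1.0], size=lam.shape)
        c = np.where(include, sign * np.sqrt(kT3 * R / np.where(include, lam, 1.0)),
                     0.0)
        disp_mw = vecs @ c
        if excl_vec is not None:
            disp_mw = disp_mw - (disp_mw @ excl_vec) * excl_vec
        disp = (disp_mw / sqm).reshape(n, 3)
        amax = np.linalg.norm(disp, axis=1).max()
        if amax > config.max_displacement:
            disp *= config.max_displacement / amax
        out.append(structure.with_coordinates(structure.coordinates + disp))
    return out
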