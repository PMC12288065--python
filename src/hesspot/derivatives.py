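"""Forces and Hessians of the predicted energy, plus a finite-difference oracle.

The predicted energy is a composition  E = sum_a net_{Z_a}(G_a(x)); its
force and Hessian follow from the chain rule:

    F_m      = - sum_k dE/dG_k * dG_k/dx_m
    H_mn     =   sum_k [ dG_k/dx_n * d2E/dG_k dG_l * dG_l/dx_m
                       + dE/dG_k * d2G_k/dx_n dx_m ]

computed here by propagating second-order jets through descriptor and
network (no finite differences anywhere in the prediction path).  The
finite-difference oracle below is deliberately independent of that path
and exists for tests and diagnostics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model import PotentialModel
from .structures import LabeledStructure, PaddedBatch, unbatch


class DerivativeError(RuntimeError):
    pass


@dataclass
class DerivativeBundle:
    """Energies, forces, and Hessians over a padded batch, with masks."""

    energies: np.ndarray                      # (M,)
    forces: Optional[np.ndarray]              # (M, N, 3)
    hessians: Optional[np.ndarray]            # (M, 3N, 3N)
    atom_mask: np.ndarray                     # (M, N)

    @property
    def coord_mask(self) -> np.ndarray:
        return np.repeat(self.atom_mask, 3, axis=1)


def _as_structures(batch) -> list[LabeledStructure]:
    if isinstance(batch, PaddedBatch):
        return unbatch(batch)
    if isinstance(batch, LabeledStructure):
        return [batch]
    return list(batch)


def predict_bundle(model: PotentialModel, batch, order: int = 2) -> DerivativeBundle:
    """Energies and derivatives up to ``order`` for all molecules in one pass."""
    structures = _as_structures(batch)
    (E, dE, d2E), fb = model.predict(structures, order=order)
    M = len(structures)
    N = fb.D // 3
    mask = np.zeros((M, N), dtype=bool)
    for m, s in enumerate(structures):
        mask[m, : s.n_atoms] = True
    forces = None
    if dE is not None:
        if not np.all(np.isfinite(dE)):
            bad = np.nonzero(~np.isfinite(dE).all(axis=1))[0]
            raise DerivativeError(f"non-finite gradient for molecule(s) {bad.tolist()}")
        forces = (-dE).reshape(M, N, 3)
        forces[~mask] = 0.0
    hessians = None
    if d2E is not None:
        if not np.all(np.isfinite(d2E)):
            bad = np.nonzero(~np.isfinite(d2E).reshape(M, -1).all(axis=1))[0]
            raise DerivativeError(f"non-finite Hessian for molecule(s) {bad.tolist()}")
        hessians = 0.5 * (d2E + np.swapaxes(d2E, 1, 2))
        cm = np.repeat(mask, 3, axis=1)
        hessians *= cm[:, :, None] * cm[:, None, :]
    return DerivativeBundle(E, forces, hessians, mask)


def predict_forces(model: PotentialModel, batch) -> np.ndarray:
    """(M, N, 3) forces = negative energy gradient; padded entries zero."""
    return predict_bundle(model, batch, order=1).forces


def predict_hessians(model: PotentialModel, batch) -> np.ndarray:
    """(M, 3N, 3N) symmetric Hessians; padded blocks zero."""
    return predict_bundle(model, batch, order=2).hessians


# ---------------------------------------------------------------------------
# finite-difference oracle (tests/diagnostics only)
# ---------------------------------------------------------------------------

def finite_difference_oracle(energy_fn: Callable[[np.ndarray], float],
                             structure: LabeledStructure,
                             step: float = 1e-3,
                             force_fn=None):
    """Central-difference forces and Hessian of a scalar energy function.

    ``energy_fn`` maps an (n, 3) coordinate array to a scalar.  The Hessian
    is built from gradient differences when no ``force_fn`` is supplied and
    symmetrized as (H + H^T)/2; a strong residual asymmetry indicates
    cancellation from a too-small step and triggers a warning.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x0 = structure.coordinates
    n = x0.shape[0]

    def grad(x):
        g = np.zeros(3 * n)
        for i in range(3 * n):
            xp = x.ravel().copy()
            xm = x.ravel().copy()
            xp[i] += step
            xm[i] -= step
            g[i] = (energy_fn(xp.reshape(n, 3)) - energy_fn(xm.reshape(n, 3))) / (2 * step)
        return g

    g0 = grad(x0)
    forces = -g0.reshape(n, 3)
    H = np.zeros((3 * n, 3 * n))
    for i in range(3 * n):
        xp = x0.ravel().copy()
        xm = x0.ravel().copy()
        xp[i] += step
        xm[i] -= step
        if force_fn is not None:
            gp = -np.asarray(force_fn(xp.reshape(n, 3))).ravel()
            gm = -np.asarray(force_fn(xm.reshape(n, 3))).ravel()
        else:
            gp = grad(xp.reshape(n, 3))
            gm = grad(xm.reshape(n, 3))
        H[:, i] = (gp - gm) / (2 * step)
    asym = np.abs(H - H.T).max() / max(np.abs(H).max(), 1e-300)
    if asym > 1e-3:
        warnings.warn(
            f"finite-difference Hessian asymmetry {asym:.2e}; "
            "step may be too small (cancellation)", RuntimeWarning)
    return forces, 0.5 * (H + H.T)
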