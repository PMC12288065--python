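"""Vibrational analysis from mass-weighted Hessians, without projection.

Frequencies come from diagonalizing H_mw = M^(-1/2) H M^(-1/2) directly —
translational and rotational modes are *not* projected out, so every
geometry yields all 3N modes (three of them near zero for any
translation-invariant potential; more may be imaginary off stationary
points).  Imaginary frequencies are reported as negative numbers:
nu = sign(lambda) sqrt(|lambda|) / (2 pi c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import C_CM_FS, MW_EIGVAL_TO_OMEGA_SQ


class VibrationsError(ValueError):
    pass


def mass_weighted_hessian(H: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """M^(-1/2) H M^(-1/2) with the per-coordinate diagonal mass matrix."""
    H = np.asarray(H, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise VibrationsError("masses must be positive")
    inv_sq = 1.0 / np.sqrt(np.repeat(masses, 3))
    return H * np.outer(inv_sq, inv_sq)


def frequencies(H: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """All 3N harmonic frequencies in cm^-1, sorted ascending.

    Input units: H in kcal/(mol A^2), masses in amu.  Negative values
    encode imaginary modes.
    """
    Hmw = mass_weighted_hessian(H, masses)
    lam = np.linalg.eigvalsh(0.5 * (Hmw + Hmw.T))
    omega = np.sqrt(np.abs(lam) * MW_EIGVAL_TO_OMEGA_SQ)   # rad/fs
    nu = np.sign(lam) * omega / (2.0 * np.pi * C_CM_FS)    # cm^-1
    return np.sort(nu)


def normal_modes(H: np.ndarray, masses: np.ndarray):
    """(frequencies cm^-1, mass-weighted eigenvectors as columns), sorted."""
    Hmw = mass_weighted_hessian(H, masses)
    lam, vecs = np.linalg.eigh(0.5 * (Hmw + Hmw.T))
    omega = np.sqrt(np.abs(lam) * MW_EIGVAL_TO_OMEGA_SQ)
    nu = np.sign(lam) * omega / (2.0 * np.pi * C_CM_FS)
    order = np.argsort(nu)
    return nu[order], vecs[:, order]


@dataclass
class VibrationalSpectrum:
    """Per-geometry sorted frequencies along a path."""

    arc: np.ndarray                 # per-geometry arc coordinate
    freqs: np.ndarray               # (n_geometries, 3N), sorted per row
    source: str                     # "reference" or "model"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs,
                          columns=[f"mode_{k}" for k in range(self.freqs.shape[1])])
        df.insert(0, "arc", self.arc)
        return df


def spectrum_along_path(hessian_source, images: Sequence,
                        source_tag: str = "model",
                        track_modes: bool = False) -> VibrationalSpectrum:
    """Frequencies at every image of a reaction path.

    ``hessian_source`` is either a reference force field (``evaluate``
    method) or a trained potential (``predict``); images carry an "arc"
    info key when they come from an IRC or MEP.  By default modes are
    sorted by magnitude per geometry; with ``track_modes`` each image's
    modes are reordered by maximal eigenvector overlap with the previous
    image, so avoided crossings follow one physical mode per column.
    """
    freqs = []
    arcs = []
    prev_vecs = None
    for im in images:
        if hasattr(hessian_source, "evaluate"):
            _, _, H = hessian_source.evaluate(im.coordinates, order=2)
        else:
            from .derivatives import predict_bundle
            H = predict_bundle(hessian_source, [im], order=2).hessians[0]
        nu, vecs = normal_modes(H, im.masses)
        if track_modes and prev_vecs is not None:
            order = _overlap_assignment(prev_vecs, vecs)
            nu, vecs = nu[order], vecs[:, order]
        freqs.append(nu)
        prev_vecs = vecs
        arcs.append(float(im.info.get("arc", len(arcs))))
    return VibrationalSpectrum(np.array(arcs), np.stack(freqs), source_tag)


def _overlap_assignment(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Column order of ``cur`` maximizing total |overlap| with ``prev``."""
    from scipy.optimize import linear_sum_assignment
    cost = -np.abs(prev.T @ cur)
    _, cols = linear_sum_assignment(cost)
    return cols
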