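"""Nudged-elastic-band minimum-energy-path optimization with climbing image.

Images between two (pre-optimized) endpoints are relaxed under projected
forces: the true force perpendicular to the path tangent plus a spring
force along it (improved upwind tangent).  With ``climb`` enabled the
highest-energy image feels the inverted parallel true force and no
springs, driving it to the saddle point.  The optimizer is FIRE — NEB
forces are not the gradient of a scalar objective, so a force-based
minimizer is required.

The spring constant is accepted in eV/A^2 (default 50, the conventional
choice) and converted internally to kcal/(mol A^2); the convergence
threshold is on the max per-atom projected-force norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import EV_TO_KCALMOL
from .structures import LabeledStructure


class NEBError(RuntimeError):
    pass


@dataclass
class MEP:
    """Optimized path: images, model energies, arc coordinate (TS at 0)."""

    images: list[LabeledStructure]
    energies: np.ndarray
    arc: np.ndarray
    spring_constant_ev: float
    converged: bool
    final_fmax: float
    climbing_index: Optional[int] = None
    n_iterations: int = 0


def interpolate_path(reactant: LabeledStructure, product: LabeledStructure,
                     n_images: int) -> list[LabeledStructure]:
    """Linear interpolation in Cartesian coordinates; endpoints exact copies."""
    if reactant.species != product.species:
        raise NEBError(f"species mismatch: {reactant.species} vs {product.species}")
    if n_images < 3:
        raise NEBError("need at least 3 images")
    out = []
    for k in range(n_images):
        f = k / (n_images - 1)
        out.append(LabeledStructure(
            reactant.species,
            (1.0 - f) * reactant.coordinates + f * product.coordinates))
    return out


def _tangents(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Improved (energy-weighted upwind) tangent estimates for inner images."""
    n = len(X)
    tau = np.zeros_like(X)
    for i in range(1, n - 1):
        dplus = X[i + 1] - X[i]
        dminus = X[i] - X[i - 1]
        if E[i + 1] > E[i] > E[i - 1]:
            t = dplus
        elif E[i + 1] < E[i] < E[i - 1]:
            t = dminus
        else:
            dEmax = max(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
            dEmin = min(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
            if E[i + 1] > E[i - 1]:
                t = dplus * dEmax + dminus * dEmin
            else:
                t = dplus * dEmin + dminus * dEmax
        tau[i] = t / np.linalg.norm(t)
    return tau


def optimize_mep(calculator, images: list[LabeledStructure],
                 spring_k_ev: float = 50.0, climb: bool = True,
                 fmax_tol_ev: float = 0.05, max_iterations: int = 3000,
                 climb_after: int = 5) -> MEP:
    """Relax a band of images to the minimum-energy path.

    fmax_tol_ev is the eV/A threshold on the largest per-atom NEB-force
    norm.  Non-convergence is *reported*, not raised: the returned MEP
    carries converged=False and the final force measure.
    """
    species = images[0].species
    nim = len(images)
    X = np.stack([im.coordinates.ravel() for im in images])
    k_spring = spring_k_ev * EV_TO_KCALMOL
    fmax_tol = fmax_tol_ev * EV_TO_KCALMOL

    def true_forces():
        E = np.zeros(nim)
        F = np.zeros_like(X)
        for i in range(nim):
            e, f = calculator.energy_and_forces(
                LabeledStructure(species, X[i].reshape(-1, 3)))
            E[i], F[i] = e, f.ravel()
        return E, F

    # FIRE parameters (standard values)
    dt, dt_max = 0.02, 0.12
    alpha, alpha0 = 0.1, 0.1
    f_inc, f_dec, f_alpha, n_min = 1.1, 0.5, 0.99, 5
    v = np.zeros_like(X)
    n_pos = 0
    climbing_index = None
    fmax = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        E, F = true_forces()
        tau = _tangents(X, E)
        Fneb = np.zeros_like(X)
        if climb and it > climb_after:
            climbing_index = int(np.argmax(E[1:-1])) + 1
        for i in range(1, nim - 1):
            t = tau[i]
            if i == climbing_index:
                Fneb[i] = F[i] - 2.0 * (F[i] @ t) * t
                continue
            f_perp = F[i] - (F[i] @ t) * t
            f_spring = k_spring * (np.linalg.norm(X[i + 1] - X[i])
                                   - np.linalg.norm(X[i] - X[i - 1])) * t
            Fneb[i] = f_perp + f_spring
        fmax = max(np.linalg.norm(Fneb[i].reshape(-1, 3), axis=1).max()
                   for i in range(1, nim - 1))
        if fmax < fmax_tol and (climbing_index is not None or not climb):
            break
        # FIRE update on the inner images
        P = float((Fneb * v).sum())
        if P > 0:
            n_pos += 1
            vnorm = np.linalg.norm(v)
            fnorm = np.linalg.norm(Fneb)
            if fnorm > 0:
                v = (1 - alpha) * v + alpha * vnorm * Fneb / fnorm
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_pos = 0
        v = v + dt * Fneb
        X[1:-1] = X[1:-1] + dt * v[1:-1]

    E, _F = true_forces()
    out_images = [LabeledStructure(species, X[i].reshape(-1, 3), energy=float(E[i]),
                                   info={}) for i in range(nim)]
    # arc coordinate: cumulative Cartesian path length, zero at the maximum
    seg = np.linalg.norm(np.diff(X, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s = s - s[int(np.argmax(E))]
    for im, a in zip(out_images, s):
        im.info["arc"] = float(a)
    done = bool(fmax < fmax_tol and (climbing_index is not None or not climb))
    return MEP(out_images, E, s, spring_k_ev,
               converged=done, final_fmax=float(fmax),
               climbing_index=climbing_index, n_iterations=it)


def barrier_height(mep: MEP, reference_end: str = "reactant",
                   force: bool = False) -> float:
    """Max image energy minus the chosen endpoint energy (kcal/mol)."""
    if not mep.converged and not force:
        raise NEBError("MEP not converged; pass force=True to evaluate anyway")
    if reference_end == "reactant":
        ref = mep.energies[0]
    elif reference_end == "product":
        ref = mep.energies[-1]
    else:
        raise ValueError("reference_end must be 'reactant' or 'product'")
    return float(mep.energies.max() - ref)
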