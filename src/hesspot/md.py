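"""Langevin dynamics with the iterative-heating stability protocol.

A model's dynamical stability is probed by geometry-optimizing a molecule
on the model surface, then running Langevin MD starting at 5 K and raising
the target temperature by a fixed increment after every stage until a
*bond-distortion* failure criterion fires: failure occurs as soon as the
mean distance of any monitored pair over the trailing 50 steps exceeds
1.5x — or drops below 0.75x — its equilibrium value at the optimized
geometry (strict inequalities).  The failure temperature of a model is the
temperature of the stage in which the criterion first fired.

Default protocol: 5 K start, +5 K increments, 5 ps (10,000 step) stages,
0.5 fs time step, friction 0.01 fs^-1.  The integrator is BAOAB Langevin;
velocities persist across temperature increments.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import COVALENT_RADII, FORCE_PER_AMU_TO_ACC, KB_KCALMOL
from .structures import LabeledStructure


@dataclass(frozen=True)
class RampProtocol:
    """Iterative-heating schedule and integrator settings."""

    start_temperature: float = 5.0     # K
    increment: float = 5.0             # K
    stage_ps: float = 5.0
    dt_fs: float = 0.5
    friction: float = 0.01             # fs^-1
    temperature_cap: float = 2500.0    # K
    seed: int = 0
    pair_mode: str = "bonded"          # or "all"
    bond_scale: float = 1.3            # covalent-radii factor for bond detection

    def __post_init__(self):
        if min(self.start_temperature, self.increment, self.stage_ps,
               self.dt_fs, self.friction, self.temperature_cap) <= 0:
            raise ValueError("all protocol parameters must be positive")

    @property
    def stage_steps(self) -> int:
        return int(round(self.stage_ps * 1000.0 / self.dt_fs))


@dataclass
class StabilityResult:
    """Outcome of one temperature ramp."""

    failure_temperature: Optional[float]   # K; None if the cap was reached
    total_time_ps: float
    failed_on_optimization: bool = False
    failing_pair: Optional[tuple[int, int]] = None
    direction: Optional[str] = None        # "stretch" or "compression"
    cap_reached: bool = False


@dataclass
class MDState:
    coords: np.ndarray        # (n, 3) angstrom
    velocities: np.ndarray    # (n, 3) angstrom/fs
    forces: np.ndarray        # (n, 3) kcal/(mol A)


def maxwell_boltzmann_velocities(masses: np.ndarray, T: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """(n, 3) velocities in angstrom/fs at temperature T."""
    sigma = np.sqrt(KB_KCALMOL * T * FORCE_PER_AMU_TO_ACC / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * (masses[:, None] * velocities ** 2).sum() / FORCE_PER_AMU_TO_ACC
    return 2.0 * ke / (3.0 * len(masses) * KB_KCALMOL)


def langevin_stage(calculator, structure_species, state: MDState,
                   masses: np.ndarray, T: float, protocol: RampProtocol,
                   rng: np.random.Generator, n_steps: Optional[int] = None,
                   step_callback=None) -> MDState:
    """BAOAB Langevin integration at target temperature T.

    ``calculator.energy_and_forces(structure)`` supplies forces.  The
    callback (if given) is invoked after every step with the current
    coordinates and may return True to terminate the stage early.
    """
    dt = protocol.dt_fs
    gamma = protocol.friction
    n_steps = protocol.stage_steps if n_steps is None else n_steps
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB_KCALMOL * T * FORCE_PER_AMU_TO_ACC / masses)
    inv_m = FORCE_PER_AMU_TO_ACC / masses
    x, v, F = state.coords, state.velocities, state.forces
    for step in range(n_steps):
        v = v + 0.5 * dt * F * inv_m[:, None]
        x = x + 0.5 * dt * v
        v = c1 * v + c2[:, None] * rng.standard_normal(x.shape)
        x = x + 0.5 * dt * v
        try:
            _, F = calculator.energy_and_forces(
                LabeledStructure(structure_species, x))
        except Exception as exc:
            raise RuntimeError(f"force evaluation failed at step {step}") from exc
        v = v + 0.5 * dt * F * inv_m[:, None]
        if step_callback is not None and step_callback(x):
            break
    return MDState(x, v, F)


# ---------------------------------------------------------------------------
# failure criterion
# ---------------------------------------------------------------------------

def detect_bonds(structure: LabeledStructure, scale: float = 1.3
                 ) -> list[tuple[int, int]]:
    """Pairs within ``scale`` times the covalent-radii sum."""
    coords = structure.coordinates
    out = []
    for i in range(structure.n_atoms):
        for j in range(i + 1, structure.n_atoms):
            rcut = scale * (COVALENT_RADII[structure.species[i]]
                            + COVALENT_RADII[structure.species[j]])
            if np.linalg.norm(coords[i] - coords[j]) < rcut:
                out.append((i, j))
    return out


def failure_check(window: np.ndarray, ref_distances: np.ndarray):
    """Bond-distortion verdict on a trailing window of pair distances.

    ``window`` is (50, n_pairs); fails if any pair's window mean exceeds
    1.5x or falls below 0.75x its reference distance (strict inequalities).
    Returns (failed, pair_index, direction).
    """
    window = np.asarray(window, dtype=float)
    if window.shape[0] != 50:
        raise ValueError(f"window must hold exactly 50 steps, got {window.shape[0]}")
    mean = window.mean(axis=0)
    stretched = mean > 1.5 * ref_distances
    compressed = mean < 0.75 * ref_distances
    if stretched.any():
        return True, int(np.argmax(stretched)), "stretch"
    if compressed.any():
        return True, int(np.argmax(compressed)), "compression"
    return False, None, None


# ---------------------------------------------------------------------------
# the ramp
# ---------------------------------------------------------------------------

def optimize_on_model(calculator, structure: LabeledStructure,
                      gtol: float = 0.5, maxiter: int = 500):
    """Geometry optimization on the calculator's surface (L-BFGS).

    Returns (optimized structure, converged flag).
    """
    species = structure.species
    n = structure.n_atoms

    def fun(xflat):
        e, f = calculator.energy_and_forces(
            LabeledStructure(species, xflat.reshape(n, 3)))
        return e, -f.ravel()

    res = minimize(fun, structure.coordinates.ravel(), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol * 0.1})
    opt = LabeledStructure(species, res.x.reshape(n, 3))
    _, f = calculator.energy_and_forces(opt)
    return opt, bool(np.abs(f).max() < gtol)


def temperature_ramp(calculator, structure: LabeledStructure,
                     protocol: RampProtocol,
                     bonds: Optional[Sequence[tuple[int, int]]] = None
                     ) -> StabilityResult:
    """Run the iterative-heating protocol until failure or the cap.

    ``structure`` should be (near) a minimum of the underlying reference
    surface; it is re-optimized on the model first.  If the model
    optimization collapses the molecule (any monitored pair drifting past
    the failure thresholds relative to the input geometry), the run is
    reported as failed on optimization with zero simulated time.
    """
    masses = structure.masses
    if bonds is None:
        bonds = detect_bonds(structure, protocol.bond_scale)
        if protocol.pair_mode == "all" or not bonds:
            bonds = [(i, j) for i in range(structure.n_atoms)
                     for j in range(i + 1, structure.n_atoms)]
    pairs = np.array(bonds)

    def distances(x):
        return np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)

    d_input = distances(structure.coordinates)
    opt, converged = optimize_on_model(calculator, structure)
    d_eq = distances(opt.coordinates)
    if (not converged) or np.any(d_eq > 1.5 * d_input) or np.any(d_eq < 0.75 * d_input):
        return StabilityResult(failure_temperature=0.0, total_time_ps=0.0,
                               failed_on_optimization=True)

    rng = np.random.default_rng(np.random.SeedSequence([int(protocol.seed), 0x4d44]))
    _, F0 = calculator.energy_and_forces(opt)
    state = MDState(opt.coordinates.copy(),
                    maxwell_boltzmann_velocities(masses, protocol.start_temperature, rng),
                    F0)
    window: deque = deque(maxlen=50)
    steps_run = 0
    T = protocol.start_temperature
    while T <= protocol.temperature_cap:
        verdict = {"failed": False}

        def callback(x):
            nonlocal steps_run
            steps_run += 1
            window.append(distances(x))
            if len(window) == 50:
                failed, pair, direction = failure_check(np.array(window), d_eq)
                if failed:
                    verdict.update(failed=True, pair=pair, direction=direction)
                    return True
            return False

        state = langevin_stage(calculator, structure.species, state, masses,
                               T, protocol, rng, step_callback=callback)
        if verdict["failed"]:
            return StabilityResult(
                failure_temperature=T,
                total_time_ps=steps_run * protocol.dt_fs / 1000.0,
                failing_pair=tuple(pairs[verdict["pair"]]),
                direction=verdict["direction"])
        T += protocol.increment
    return StabilityResult(failure_temperature=None,
                           total_time_ps=steps_run * protocol.dt_fs / 1000.0,
                           cap_reached=True)
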