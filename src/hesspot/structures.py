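"""Structure and padded-batch data model.

A :class:`LabeledStructure` is one gas-phase molecule with optional
energy/force/Hessian labels in the internal unit system (kcal/mol, angstrom).
A :class:`PaddedBatch` stacks M molecules padded to a common atom count N,
with explicit validity masks; all label entries at padded positions are
exactly zero, and padded Hessian rows *and* columns are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import ATOMIC_MASSES

#: Species token used for padded (absent) atom slots; never a real element.
PAD_SPECIES = ""


class StructureError(ValueError):
    """Raised for invalid structures or inconsistent batches."""


def masses_for(species: Sequence[str]) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASSES[s] for s in species], dtype=float)
    except KeyError as exc:
        raise StructureError(f"unknown element {exc.args[0]!r}") from None


@dataclass
class LabeledStructure:
    """One molecule with optional energy / force / Hessian labels.

    coordinates are (n_atoms, 3) angstrom; energy kcal/mol; forces
    (n_atoms, 3) kcal/(mol A); hessian (3n, 3n) kcal/(mol A^2).
    """

    species: tuple[str, ...]
    coordinates: np.ndarray
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    hessian: Optional[np.ndarray] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = self.n_atoms
        if n < 1:
            raise StructureError("structure needs at least one atom")
        if len(self.species) != n:
            raise StructureError(
                f"species length {len(self.species)} != atom count {n}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite coordinates")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(n, 3)
            if not np.all(np.isfinite(self.forces)):
                raise StructureError("non-finite forces")
        if self.hessian is not None:
            H = np.asarray(self.hessian, dtype=float)
            if H.shape != (3 * n, 3 * n):
                raise StructureError(
                    f"hessian shape {H.shape} != ({3*n}, {3*n})"
                )
            scale = max(np.abs(H).max(), 1.0)
            if np.abs(H - H.T).max() > 1e-8 * scale:
                raise StructureError("hessian not symmetric within 1e-8 relative")
            self.hessian = H
        if self.energy is not None:
            self.energy = float(self.energy)
            if not np.isfinite(self.energy):
                raise StructureError("non-finite energy")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return masses_for(self.species)

    def with_coordinates(self, coords: np.ndarray) -> "LabeledStructure":
        """Copy with new coordinates and all labels dropped."""
        return LabeledStructure(self.species, np.array(coords, dtype=float))


@dataclass
class PaddedBatch:
    """M molecules padded to N atoms with explicit masks."""

    species: list[tuple[str, ...]]          # per-molecule, padded with PAD_SPECIES
    coordinates: np.ndarray                 # (M, N, 3)
    atom_mask: np.ndarray                   # (M, N) bool
    energies: Optional[np.ndarray] = None   # (M,)
    forces: Optional[np.ndarray] = None     # (M, N, 3)
    hessians: Optional[np.ndarray] = None   # (M, 3N, 3N)

    @property
    def n_molecules(self) -> int:
        return self.coordinates.shape[0]

    @property
    def max_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_atoms_per_molecule(self) -> np.ndarray:
        return self.atom_mask.sum(axis=1)

    @property
    def coord_mask(self) -> np.ndarray:
        """(M, 3N) boolean mask over flattened coordinates."""
        return np.repeat(self.atom_mask, 3, axis=1)


def build_batch(structures: Sequence[LabeledStructure]) -> PaddedBatch:
    """Pad a nonempty list of structures to a common atom count.

    Each label kind (energy / forces / hessian) must be present for all
    structures or absent for all.
    """
    if len(structures) == 0:
        raise StructureError("cannot batch an empty structure list")
    M = len(structures)
    N = max(s.n_atoms for s in structures)

    for name in ("energy", "forces", "hessian"):
        present = [getattr(s, name) is not None for s in structures]
        if any(present) and not all(present):
            raise StructureError(f"inconsistent availability of label {name!r}")

    species = []
    coords = np.zeros((M, N, 3))
    mask = np.zeros((M, N), dtype=bool)
    for i, s in enumerate(structures):
        n = s.n_atoms
        species.append(tuple(s.species) + (PAD_SPECIES,) * (N - n))
        coords[i, :n] = s.coordinates
        mask[i, :n] = True

    batch = PaddedBatch(species, coords, mask)
    if structures[0].energy is not None:
        batch.energies = np.array([s.energy for s in structures])
    if structures[0].forces is not None:
        batch.forces = np.zeros((M, N, 3))
        for i, s in enumerate(structures):
            batch.forces[i, : s.n_atoms] = s.forces
    if structures[0].hessian is not None:
        batch.hessians = np.zeros((M, 3 * N, 3 * N))
        for i, s in enumerate(structures):
            d = 3 * s.n_atoms
            batch.hessians[i, :d, :d] = s.hessian
    return batch


def unbatch(batch: PaddedBatch) -> list[LabeledStructure]:
    """Recover the input structures of :func:`build_batch` bit-exactly."""
    out = []
    for i in range(batch.n_molecules):
        n = int(batch.atom_mask[i].sum())
        out.append(
            LabeledStructure(
                species=batch.species[i][:n],
                coordinates=batch.coordinates[i, :n].copy(),
                energy=None if batch.energies is None else float(batch.energies[i]),
                forces=None if batch.forces is None else batch.forces[i, :n].copy(),
                hessian=None
                if batch.hessians is None
                else batch.hessians[i, : 3 * n, : 3 * n].copy(),
            )
        )
    return out


def mask_counts(batch: PaddedBatch) -> tuple[int, int, int]:
    """(M, n_F, n_H): molecule, force-element and Hessian-element counts.

    Padded elements are excluded: n_F = 3 * sum_i n_atoms(i),
    n_H = sum_i (3 n_atoms(i))**2.
    """
    n = batch.n_atoms_per_molecule
    return int(batch.n_molecules), int(3 * n.sum()), int(((3 * n) ** 2).sum())
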