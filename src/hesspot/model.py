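"""Per-element atomic networks summed to molecular energies, plus ensembles.

The potential follows the high-dimensional neural-network form: every
element of the alphabet has its own feed-forward network mapping an atom's
environment vector to an atomic energy partition; the molecular energy is
the sum of atomic partitions plus fitted per-element reference energies
(self-energy removal).  Ensembles of independently initialized members
provide mean +- standard-deviation predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .descriptor import AEVSpec, featurize_structure
from .nn import init_params, mlp_jet_forward
from .structures import LabeledStructure, PaddedBatch, unbatch


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ArchConfig:
    """Network architecture: hidden layer sizes per element network."""

    hidden: tuple[int, ...] = (64, 64)
    aev_spec: AEVSpec = field(default_factory=AEVSpec)


# ---------------------------------------------------------------------------
# featurized batches (shared by prediction and training)
# ---------------------------------------------------------------------------

@dataclass
class FeaturizedBatch:
    """Descriptor jets for a set of molecules, grouped by element.

    ``element_rows[e] = (mol_idx, G, Gr, Hs)`` where G is (na, L), Gr is
    (na, D, L), Hs is (na, D, D, L); D = 3 * max atom count.  Computing
    this once and reusing it across fits is the main cost saver of the
    training harness — descriptor derivatives do not depend on weights.
    """

    spec: AEVSpec
    order: int
    n_mol: int
    n_atoms: np.ndarray
    D: int
    coord_mask: np.ndarray                 # (M, D) bool
    element_rows: dict
    element_counts: np.ndarray             # (M, n_elements)
    energies: Optional[np.ndarray] = None
    forces_flat: Optional[np.ndarray] = None     # (M, D), zero-padded
    hessians: Optional[np.ndarray] = None        # (M, D, D), zero-padded

    def astype(self, dtype) -> "FeaturizedBatch":
        """Copy with all descriptor and label arrays cast to ``dtype``.

        Training runs in float32 by default (the loss gradient tolerates
        it); prediction stays float64.
        """
        rows = {e: (mi, G.astype(dtype),
                    None if Gr is None else Gr.astype(dtype),
                    None if Hs is None else Hs.astype(dtype))
                for e, (mi, G, Gr, Hs) in self.element_rows.items()}
        return FeaturizedBatch(
            self.spec, self.order, self.n_mol, self.n_atoms, self.D,
            self.coord_mask, rows, self.element_counts,
            None if self.energies is None else self.energies.astype(dtype),
            None if self.forces_flat is None else self.forces_flat.astype(dtype),
            None if self.hessians is None else self.hessians.astype(dtype),
        )

    def subset(self, idx: Sequence[int]) -> "FeaturizedBatch":
        idx = np.asarray(idx)
        remap = -np.ones(self.n_mol, dtype=int)
        remap[idx] = np.arange(len(idx))
        rows = {}
        for e, (mi, G, Gr, Hs) in self.element_rows.items():
            keep = np.isin(mi, idx)
            if not keep.any():
                continue
            rows[e] = (remap[mi[keep]], G[keep],
                       None if Gr is None else Gr[keep],
                       None if Hs is None else Hs[keep])
        return FeaturizedBatch(
            self.spec, self.order, len(idx), self.n_atoms[idx], self.D,
            self.coord_mask[idx], rows, self.element_counts[idx],
            None if self.energies is None else self.energies[idx],
            None if self.forces_flat is None else self.forces_flat[idx],
            None if self.hessians is None else self.hessians[idx],
        )


def featurize_structures(structures: Sequence[LabeledStructure], spec: AEVSpec,
                         order: int) -> FeaturizedBatch:
    M = len(structures)
    n_atoms = np.array([s.n_atoms for s in structures])
    N = int(n_atoms.max())
    D = 3 * N
    coord_mask = np.zeros((M, D), dtype=bool)
    counts = np.zeros((M, spec.n_elements), dtype=int)
    per_elem: dict = {e: [] for e in spec.elements}
    for m, s in enumerate(structures):
        coord_mask[m, : 3 * s.n_atoms] = True
        G, dG, d2G = featurize_structure(s, spec, order=order, pad_to=N)
        ei = spec.element_index(s.species)
        counts[m] = np.bincount(ei, minlength=spec.n_elements)
        for a, e_idx in enumerate(ei):
            per_elem[spec.elements[e_idx]].append((
                m, G[a],
                None if dG is None else dG[a].T.copy(),          # (D, L)
                None if d2G is None else d2G[a].transpose(1, 2, 0).copy(),
            ))
    rows = {}
    for e, items in per_elem.items():
        if not items:
            continue
        mi = np.array([it[0] for it in items])
        G = np.stack([it[1] for it in items])
        Gr = None if order < 1 else np.stack([it[2] for it in items])
        Hs = None if order < 2 else np.stack([it[3] for it in items])
        rows[e] = (mi, G, Gr, Hs)

    labels = {}
    if all(s.energy is not None for s in structures):
        labels["energies"] = np.array([s.energy for s in structures])
    if all(s.forces is not None for s in structures):
        F = np.zeros((M, D))
        for m, s in enumerate(structures):
            F[m, : 3 * s.n_atoms] = s.forces.ravel()
        labels["forces_flat"] = F
    if all(s.hessian is not None for s in structures):
        H = np.zeros((M, D, D))
        for m, s in enumerate(structures):
            d = 3 * s.n_atoms
            H[m, :d, :d] = s.hessian
        labels["hessians"] = H
    return FeaturizedBatch(spec, order, M, n_atoms, D, coord_mask, rows,
                           counts, **labels)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class PotentialModel:
    """Per-element networks + reference energies on one descriptor spec."""

    spec: AEVSpec
    hidden: tuple[int, ...]
    params: dict                                   # element -> [(W, b), ...]
    ref_energies: dict                             # element -> kcal/mol
    feat_shift: dict                               # element -> (L,)
    feat_scale: dict                               # element -> (L,)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def initialize(cls, arch: ArchConfig, seed) -> "PotentialModel":
        spec = arch.aev_spec
        L = spec.length
        params, shift, scale, ref = {}, {}, {}, {}
        ss = seed if isinstance(seed, np.random.SeedSequence) \
            else np.random.SeedSequence(seed)
        for e, child in zip(spec.elements, ss.spawn(spec.n_elements)):
            rng = np.random.default_rng(child)
            params[e] = init_params(rng, [L, *arch.hidden, 1])
            shift[e] = np.zeros(L)
            scale[e] = np.ones(L)
            ref[e] = 0.0
        return cls(spec, tuple(arch.hidden), params, ref, shift, scale,
                   provenance={"seed_entropy": ss.entropy})

    # -- forward over a featurized batch -------------------------------
    def forward(self, fb: FeaturizedBatch, order: Optional[int] = None,
                with_cache: bool = False):
        """(E, dE, d2E[, caches]); dE/d2E None below the requested order."""
        order = fb.order if order is None else min(order, fb.order)
        M, D = fb.n_mol, fb.D
        E = fb.element_counts.astype(float) @ np.array(
            [self.ref_energies[e] for e in self.spec.elements])
        dE = np.zeros((M, D)) if order >= 1 else None
        d2E = np.zeros((M, D, D)) if order >= 2 else None
        caches = {}
        for e, (mi, G, Gr, Hs) in fb.element_rows.items():
            if e not in self.params:
                raise ModelError(f"no network for element {e!r}")
            scale = self.feat_scale[e]
            Gh = (G - self.feat_shift[e]) / scale
            Grh = None if (order < 1 or Gr is None) else Gr / scale
            Hsh = None if (order < 2 or Hs is None) else Hs / scale
            f, fg, fh, cache = mlp_jet_forward(self.params[e], Gh, Grh, Hsh)
            np.add.at(E, mi, f)
            if dE is not None:
                np.add.at(dE, mi, fg)
            if d2E is not None:
                np.add.at(d2E, mi, fh)
            if with_cache:
                caches[e] = (mi, cache)
        if d2E is not None:
            d2E = 0.5 * (d2E + np.swapaxes(d2E, 1, 2))
        if with_cache:
            return E, dE, d2E, caches
        return E, dE, d2E

    # -- user-facing prediction ----------------------------------------
    def _featurize(self, data, order: int) -> FeaturizedBatch:
        if isinstance(data, FeaturizedBatch):
            return data
        if isinstance(data, PaddedBatch):
            data = unbatch(data)
        if isinstance(data, LabeledStructure):
            data = [data]
        return featurize_structures(list(data), self.spec, order)

    def predict(self, data, order: int = 0):
        fb = self._featurize(data, order)
        return self.forward(fb, order=order), fb

    def energy_and_forces(self, structure: LabeledStructure):
        """Calculator interface used by MD / NEB / geometry optimization."""
        fb = self._featurize(structure, 1)
        E, dE, _ = self.forward(fb, order=1)
        n = structure.n_atoms
        return float(E[0]), -dE[0, : 3 * n].reshape(n, 3)


def predict_energy(model: PotentialModel,
                   batch: Union[PaddedBatch, Sequence[LabeledStructure]]) -> np.ndarray:
    """Per-molecule energies: summed atomic partitions + reference energies."""
    (E, _, _), _ = model.predict(batch, order=0)
    return E


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """Independently seeded model replicas sharing one descriptor spec."""

    members: list
    member_seeds: list

    def __post_init__(self):
        if len(self.members) < 1:
            raise ModelError("ensemble needs at least one member")

    def __len__(self):
        return len(self.members)

    @property
    def spec(self) -> AEVSpec:
        return self.members[0].spec


def init_ensemble(n_members: int, seed: int, arch: ArchConfig) -> Ensemble:
    """Deterministic ensemble: member i is reproducible from (seed, i)."""
    if n_members < 1:
        raise ModelError("n_members must be >= 1")
    seeds = [(int(seed), i) for i in range(n_members)]
    members = [PotentialModel.initialize(arch, s) for s in seeds]
    return Ensemble(members, seeds)


def ensemble_stats(ensemble: Ensemble, batch) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule sample mean and sample std of member energies."""
    if len(ensemble) < 2:
        raise ModelError("standard deviation needs >= 2 ensemble members")
    fb = ensemble.members[0]._featurize(batch, 0)
    preds = np.stack([m.forward(fb, order=0)[0] for m in ensemble.members])
    return preds.mean(axis=0), preds.std(axis=0, ddof=1)
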