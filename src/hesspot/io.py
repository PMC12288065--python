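"""File formats: extended XYZ, HDF5 dataset containers, model checkpoints.

Geometries and forces travel as multi-frame extended XYZ with an explicit
``units`` comment key (energies kcal/mol, forces kcal/mol/A — the reader
refuses files that do not declare them).  Hessians have no extended-XYZ
convention, so labeled datasets live in a self-describing HDF5 container
holding per-structure records plus a JSON manifest (counts, units, seed
provenance, force-field parameters).  All numeric storage is float64, so
round-trips are bit-exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import yaml

from .descriptor import AEVSpec
from .model import Ensemble, PotentialModel
from .structures import LabeledStructure

ENERGY_UNITS = "kcal/mol"
FORCE_UNITS = "kcal/mol/A"
UNITS_KEY = f"{ENERGY_UNITS},{FORCE_UNITS}"


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def write_extxyz(path, structures: Sequence[LabeledStructure]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in structures:
            props = "species:S:1:pos:R:3"
            if s.forces is not None:
                props += ":forces:R:3"
            fields = [f'Properties={props}', f'units="{UNITS_KEY}"']
            if s.energy is not None:
                fields.append(f"energy={s.energy!r}")
            for k, v in s.info.items():
                if isinstance(v, (int, float, str)):
                    fields.append(f'{k}="{v}"' if isinstance(v, str) else f"{k}={v!r}")
            fh.write(f"{s.n_atoms}\n{' '.join(fields)}\n")
            for a in range(s.n_atoms):
                row = f"{s.species[a]:2s} " + " ".join(
                    f"{c:.17g}" for c in s.coordinates[a])
                if s.forces is not None:
                    row += " " + " ".join(f"{c:.17g}" for c in s.forces[a])
                fh.write(row + "\n")


def read_extxyz(path) -> list[LabeledStructure]:
    path = Path(path)
    lines = path.read_text().splitlines()
    out = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FileFormatError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}")
        if i + 1 + n >= len(lines) + 1:
            raise FileFormatError(f"{path}:{i + 1}: truncated frame")
        header = lines[i + 1]
        kv = {m.group(1): (m.group(2) if m.group(2) is not None else m.group(3))
              for m in _KV_RE.finditer(header)}
        if "units" not in kv:
            raise FileFormatError(f"{path}:{i + 2}: missing required units key")
        if kv["units"].split(",")[0] != ENERGY_UNITS:
            raise FileFormatError(
                f"{path}:{i + 2}: unsupported units {kv['units']!r}")
        props = kv.get("Properties", "species:S:1:pos:R:3")
        cols = props.split(":")
        layout = [(cols[k], int(cols[k + 2])) for k in range(0, len(cols), 3)]
        species, coords, forces = [], [], []
        has_forces = any(name == "forces" for name, _ in layout)
        for a in range(n):
            parts = lines[i + 2 + a].split()
            expected = sum(w for _, w in layout)
            if len(parts) != expected:
                raise FileFormatError(
                    f"{path}:{i + 3 + a}: expected {expected} columns, "
                    f"got {len(parts)}")
            col = 0
            for name, width in layout:
                vals = parts[col:col + width]
                col += width
                if name == "species":
                    species.append(vals[0])
                elif name == "pos":
                    coords.append([float(v) for v in vals])
                elif name == "forces":
                    forces.append([float(v) for v in vals])
        info = {k: v for k, v in kv.items()
                if k not in ("Properties", "units", "energy")}
        out.append(LabeledStructure(
            tuple(species), np.array(coords),
            energy=float(kv["energy"]) if "energy" in kv else None,
            forces=np.array(forces) if has_forces else None,
            info=info))
        i += 2 + n
    return out


# ---------------------------------------------------------------------------
# HDF5 dataset container
# ---------------------------------------------------------------------------

def save_dataset(path, structures: Sequence[LabeledStructure],
                 manifest: Optional[dict] = None) -> None:
    path = Path(path)
    manifest = dict(manifest or {})
    manifest.setdefault("units", {"energy": ENERGY_UNITS, "forces": FORCE_UNITS,
                                  "hessian": "kcal/mol/A^2"})
    manifest["n_structures"] = len(structures)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest, default=str)
        for k, s in enumerate(structures):
            g = f.create_group(f"structure_{k:06d}")
            g.create_dataset("species", data=np.array(s.species, dtype="S8"))
            g.create_dataset("coordinates", data=s.coordinates)
            if s.energy is not None:
                g.attrs["energy"] = s.energy
            if s.forces is not None:
                g.create_dataset("forces", data=s.forces)
            if s.hessian is not None:
                g.create_dataset("hessian", data=s.hessian)
            if s.info:
                g.attrs["info"] = json.dumps(
                    {k2: v for k2, v in s.info.items()
                     if isinstance(v, (int, float, str))})


def load_dataset(path) -> tuple[list[LabeledStructure], dict]:
    path = Path(path)
    out = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        keys = sorted(k for k in f.keys() if k.startswith("structure_"))
        if len(keys) != manifest.get("n_structures", len(keys)):
            raise FileFormatError("manifest count does not match records")
        for k in keys:
            g = f[k]
            out.append(LabeledStructure(
                tuple(sp.decode() for sp in g["species"][()]),
                g["coordinates"][()],
                energy=float(g.attrs["energy"]) if "energy" in g.attrs else None,
                forces=g["forces"][()] if "forces" in g else None,
                hessian=g["hessian"][()] if "hessian" in g else None,
                info=json.loads(g.attrs["info"]) if "info" in g.attrs else {}))
    return out, manifest


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: AEVSpec) -> dict:
    return {
        "elements": list(spec.elements),
        "cutoff": spec.cutoff,
        "radial_shifts": list(spec.radial_shifts),
        "eta_radial": spec.eta_radial,
        "angular_theta_shifts": list(spec.angular_theta_shifts),
        "zeta": spec.zeta,
        "angular_radial_shifts": list(spec.angular_radial_shifts),
        "eta_angular": spec.eta_angular,
        "cutoff_fn": spec.cutoff_fn,
    }


def spec_from_dict(d: dict) -> AEVSpec:
    return AEVSpec(
        elements=tuple(d["elements"]),
        cutoff=float(d["cutoff"]),
        radial_shifts=tuple(d["radial_shifts"]),
        eta_radial=float(d["eta_radial"]),
        angular_theta_shifts=tuple(d["angular_theta_shifts"]),
        zeta=int(d["zeta"]),
        angular_radial_shifts=tuple(d["angular_radial_shifts"]),
        eta_angular=float(d["eta_angular"]),
        cutoff_fn=str(d["cutoff_fn"]),
    )


def _write_model(g: h5py.Group, model: PotentialModel) -> None:
    g.attrs["spec"] = json.dumps(_spec_to_dict(model.spec))
    g.attrs["hidden"] = json.dumps(list(model.hidden))
    g.attrs["provenance"] = json.dumps(model.provenance, default=str)
    for e in model.spec.elements:
        ge = g.create_group(f"element_{e}")
        ge.attrs["ref_energy"] = model.ref_energies[e]
        ge.create_dataset("feat_shift", data=model.feat_shift[e])
        ge.create_dataset("feat_scale", data=model.feat_scale[e])
        for li, (W, b) in enumerate(model.params[e]):
            ge.create_dataset(f"W{li}", data=W)
            ge.create_dataset(f"b{li}", data=b)


def _read_model(g: h5py.Group) -> PotentialModel:
    spec = spec_from_dict(json.loads(g.attrs["spec"]))
    hidden = tuple(json.loads(g.attrs["hidden"]))
    params, ref, shift, scale = {}, {}, {}, {}
    for e in spec.elements:
        ge = g[f"element_{e}"]
        ref[e] = float(ge.attrs["ref_energy"])
        shift[e] = ge["feat_shift"][()]
        scale[e] = ge["feat_scale"][()]
        layers = []
        li = 0
        while f"W{li}" in ge:
            layers.append((ge[f"W{li}"][()], ge[f"b{li}"][()]))
            li += 1
        params[e] = layers
    return PotentialModel(spec, hidden, params, ref, shift, scale,
                          provenance=json.loads(g.attrs["provenance"]))


def save_model(path, model: PotentialModel) -> None:
    with h5py.File(Path(path), "w") as f:
        _write_model(f.create_group("model"), model)


def load_model(path) -> PotentialModel:
    with h5py.File(Path(path), "r") as f:
        return _read_model(f["model"])


def save_ensemble(path, ensemble: Ensemble) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["n_members"] = len(ensemble)
        f.attrs["member_seeds"] = json.dumps(ensemble.member_seeds, default=str)
        for i, m in enumerate(ensemble.members):
            _write_model(f.create_group(f"member_{i:03d}"), m)


def load_ensemble(path) -> Ensemble:
    with h5py.File(Path(path), "r") as f:
        n = int(f.attrs["n_members"])
        members = [_read_model(f[f"member_{i:03d}"]) for i in range(n)]
        seeds = json.loads(f.attrs["member_seeds"])
    return Ensemble(members, seeds)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
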