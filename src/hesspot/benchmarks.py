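"""Desk-scale evaluation protocols comparing E, E-F, and E-F-H training.

Each benchmark is a scaled-down analog of a standard MLIP evaluation,
run on the synthetic reaction family where exact labels exist:

* **trend**      — train all three loss variants on an RTP (critical-point)
  dataset and compare masked RMSEs on an off-path normal-mode-sampled
  test set.
* **single_ts**  — train ensembles to a *single* transition-state
  structure and measure energy extrapolation along its IRC.
* **md_stability** — iterative-heating Langevin ramps with the
  bond-distortion failure criterion.

The configurations below are the study conditions of those protocols
(problem sizes chosen for single-CPU runs); the protocols themselves are
size-agnostic.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .descriptor import AEVSpec
from .md import RampProtocol, StabilityResult, temperature_ramp
from .model import FeaturizedBatch, featurize_structures
from .nms import NMSConfig, sample_nms
from .structures import LabeledStructure
from .surfaces import (RTPDataset, TriatomicFamily, build_rtp_dataset,
                       label_structure, trace_irc)
from .training import (LossWeights, TrainConfig, evaluate_rmse, fit)

#: loss variants in the order they are compared
VARIANTS = {
    "E": LossWeights.e_model(),
    "E-F": LossWeights.ef_model(),
    "E-F-H": LossWeights.efh_model(),
}


def benchmark_descriptor_spec() -> AEVSpec:
    """Reduced descriptor for the desk-scale protocols (5-element alphabet)."""
    return AEVSpec(
        elements=("H", "C", "N", "O", "S"),
        cutoff=4.6,
        radial_shifts=tuple(np.linspace(0.8, 3.0, 5)),
        eta_radial=8.0,
        angular_theta_shifts=(0.0, np.pi / 2, np.pi),
        angular_radial_shifts=(1.4,),
        eta_angular=2.0,
    )


def _member_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# trend benchmark (RTP training, off-path NMS evaluation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendConfig:
    """Study conditions of the loss-variant comparison."""

    n_reactions: int = 40
    n_test_reactions: int = 10
    n_members: int = 5                  # independently seeded fits per variant
    nms_temperature: float = 300.0      # K
    nms_samples_per_point: int = 3
    nms_samples_per_irc_image: int = 2
    n_irc_images: int = 4
    hidden: tuple[int, ...] = (24, 24)
    lr: float = 1e-2
    epochs: dict = field(default_factory=lambda: {
        "E": 500, "E-F": 500, "E-F-H": 700})
    patience: int = 60
    family: TriatomicFamily = field(default_factory=TriatomicFamily)


def build_offpath_test_set(dataset: RTPDataset, config: TrendConfig,
                           seed: int) -> list[LabeledStructure]:
    """Normal-mode-sampled structures around critical points and IRC images.

    At the minima all vibrational modes are sampled (the transition state's
    unstable mode cannot be thermally sampled and is skipped automatically);
    at intermediate IRC images the local path-tangent mode is excluded.
    Rigid-body modes are always excluded.  Labels are exact.
    """
    out = []
    for k, r in enumerate(dataset.reactions[: config.n_test_reactions]):
        for j, s0 in enumerate((r.reactant, r.ts, r.product)):
            cfg = NMSConfig(temperature=config.nms_temperature,
                            n_samples=config.nms_samples_per_point,
                            seed=_member_seed(seed, 10, k, j))
            for s in sample_nms(s0, s0.hessian, r.ff.masses, cfg):
                out.append(label_structure(r.ff, s.coordinates))
        path = trace_irc(r.ff, r.ts, max_images_per_branch=20)
        idx = np.linspace(3, len(path) - 4, config.n_irc_images).astype(int)
        for i in idx:
            im = path.images[i]
            cfg = NMSConfig(temperature=config.nms_temperature,
                            n_samples=config.nms_samples_per_irc_image,
                            seed=_member_seed(seed, 11, k, int(i)),
                            excluded_mode=path.tangents[i])
            for s in sample_nms(im, im.hessian, r.ff.masses, cfg):
                out.append(label_structure(r.ff, s.coordinates))
    return out


@dataclass
class TrendAssets:
    dataset: RTPDataset
    spec: AEVSpec
    fb_train: FeaturizedBatch
    test_structures: list
    fb_test: FeaturizedBatch


def build_trend_assets(config: TrendConfig, seed: int) -> TrendAssets:
    spec = benchmark_descriptor_spec()
    dataset = build_rtp_dataset(config.family, config.n_reactions,
                                seed=_member_seed(seed, 1))
    fb_train = featurize_structures(dataset.structures, spec, 2)
    test = build_offpath_test_set(dataset, config, seed)
    fb_test = featurize_structures(test, spec, 2)
    return TrendAssets(dataset, spec, fb_train, test, fb_test)


def train_variant_ensemble(assets: TrendAssets, variant: str,
                           config: TrendConfig, seed: int):
    """``n_members`` independently seeded fits of one loss variant."""
    weights = VARIANTS[variant]
    models = []
    for i in range(config.n_members):
        cfg = TrainConfig(hidden=config.hidden, lr=config.lr,
                          epochs=config.epochs[variant],
                          seed=_member_seed(seed, 2, i),
                          patience=config.patience, val_fraction=0.0)
        model, _report = fit(assets.fb_train, weights, cfg, spec=assets.spec)
        models.append(model)
    return models


def run_trend_benchmark(config: Optional[TrendConfig] = None, seed: int = 0,
                        assets: Optional[TrendAssets] = None) -> dict:
    """Median off-path RMSEs per loss variant plus the Hessian-RMSE ratio.

    Returns a dict with per-variant per-member energy/force/Hessian RMSEs,
    their medians, and the models themselves (reused by the MD benchmark).
    """
    config = config or TrendConfig()
    if assets is None:
        assets = build_trend_assets(config, seed)
    results: dict = {"config": config, "assets": assets, "variants": {}}
    for variant in VARIANTS:
        models = train_variant_ensemble(assets, variant, config, seed)
        per_member = [evaluate_rmse(m, assets.fb_test).mean for m in models]
        results["variants"][variant] = {
            "models": models,
            "energy_rmse": [p["energy_rmse"] for p in per_member],
            "force_rmse": [p["force_rmse"] for p in per_member],
            "hessian_rmse": [p["hessian_rmse"] for p in per_member],
            "median_energy_rmse": float(np.median(
                [p["energy_rmse"] for p in per_member])),
            "median_hessian_rmse": float(np.median(
                [p["hessian_rmse"] for p in per_member])),
        }
    v = results["variants"]
    results["hessian_ratio_ef_over_efh"] = (
        v["E-F"]["median_hessian_rmse"] / v["E-F-H"]["median_hessian_rmse"])
    results["energy_ordering_ok"] = (
        v["E-F-H"]["median_energy_rmse"] < v["E-F"]["median_energy_rmse"]
        < v["E"]["median_energy_rmse"])
    return results


# ---------------------------------------------------------------------------
# single-TS extrapolation benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleTSConfig:
    composition: tuple[str, str, str] = ("H", "C", "O")
    n_members: int = 4
    arc_window: float = 0.25            # amu^1/2 angstrom around the TS
    hidden: tuple[int, ...] = (24, 24)
    lr: float = 1e-2
    epochs: int = 800
    family: TriatomicFamily = field(default_factory=TriatomicFamily)


def run_single_ts_benchmark(config: Optional[SingleTSConfig] = None,
                            seed: int = 0) -> dict:
    """Train each variant to one TS structure; compare IRC energy errors.

    The measure is the mean absolute error of the ensemble-mean energy
    prediction over IRC images within ``arc_window`` of the TS.
    """
    import math
    from .surfaces import _bent_geometry, find_critical_point
    config = config or SingleTSConfig()
    ff, params = config.family.reaction_ff(config.composition)
    th1, th2 = (math.radians(t) for t in params["theta_deg"])
    th_mid = math.acos(0.5 * (math.cos(th1) + math.cos(th2)))
    r1, r2 = params["r0"]
    ts = find_critical_point(ff, _bent_geometry(r1, r2, th_mid), "saddle1")
    path = trace_irc(ff, ts, max_images_per_branch=40)
    window = np.abs(path.arc) <= config.arc_window
    images = [path.images[i] for i in np.nonzero(window)[0]]
    ref = np.array([im.energy for im in images])

    spec = benchmark_descriptor_spec()
    fb_train = featurize_structures([ts], spec, 2)
    fb_images = featurize_structures(images, spec, 0)
    out = {"arc": path.arc[window], "reference": ref, "variants": {}}
    for variant, weights in VARIANTS.items():
        preds = []
        for i in range(config.n_members):
            cfg = TrainConfig(hidden=config.hidden, lr=config.lr,
                              epochs=config.epochs,
                              seed=_member_seed(seed, 3, i),
                              patience=80, val_fraction=0.0)
            model, _ = fit(fb_train, weights, cfg, spec=spec)
            E, _, _ = model.forward(fb_images, order=0)
            preds.append(E)
        mean_pred = np.mean(preds, axis=0)
        out["variants"][variant] = {
            "mean_abs_error": float(np.abs(mean_pred - ref).mean()),
            "predictions": np.array(preds),
        }
    errs = {v: out["variants"][v]["mean_abs_error"] for v in VARIANTS}
    out["efh_lowest"] = errs["E-F-H"] == min(errs.values())
    return out


# ---------------------------------------------------------------------------
# MD stability benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MDStabilityConfig:
    """Scaled-down iterative-heating conditions (shorter stages, coarser
    increments, lower cap than the full protocol)."""

    n_molecules: int = 5
    start_temperature: float = 25.0
    increment: float = 25.0
    stage_ps: float = 0.5
    temperature_cap: float = 300.0
    dt_fs: float = 0.5
    friction: float = 0.01


def run_md_stability_benchmark(trend_results: dict,
                               config: Optional[MDStabilityConfig] = None,
                               seed: int = 0) -> dict:
    """Ramp reactant structures under E and E-F-H models plus the exact-FF
    control; report failure temperatures (cap temperature when no failure)."""
    config = config or MDStabilityConfig()
    assets: TrendAssets = trend_results["assets"]
    reactions = assets.dataset.reactions[: config.n_molecules]
    proto = RampProtocol(start_temperature=config.start_temperature,
                         increment=config.increment,
                         stage_ps=config.stage_ps,
                         dt_fs=config.dt_fs,
                         friction=config.friction,
                         temperature_cap=config.temperature_cap,
                         seed=_member_seed(seed, 4))

    def effective_T(res: StabilityResult) -> float:
        if res.cap_reached:
            return config.temperature_cap
        return float(res.failure_temperature)

    out: dict = {"config": config, "per_molecule": {}}
    for name, calc_for in (("E", lambda: trend_results["variants"]["E"]["models"][0]),
                           ("E-F-H", lambda: trend_results["variants"]["E-F-H"]["models"][0]),
                           ("exact", None)):
        temps, results = [], []
        for k, r in enumerate(reactions):
            calc = r.ff if calc_for is None else calc_for()
            res = temperature_ramp(calc, r.reactant,
                                   replace(proto, seed=_member_seed(seed, 5, k)),
                                   bonds=r.ff.bonded_pairs)
            temps.append(effective_T(res))
            results.append(res)
        out["per_molecule"][name] = {"temperatures": temps, "results": results,
                                     "median": float(np.median(temps))}
    out["efh_exceeds_e"] = (out["per_molecule"]["E-F-H"]["median"]
                            > out["per_molecule"]["E"]["median"])
    out["control_reaches_cap"] = all(
        r.cap_reached for r in out["per_molecule"]["exact"]["results"])
    return out
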