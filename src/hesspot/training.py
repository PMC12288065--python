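"""Loss terms, weight calibration, the training loop, and evaluation.

The total loss is

    L = eps_E + eta_F * eps_F + eta_H * eps_H

where eps_E / eps_F / eps_H are root-mean-square errors over molecules,
unmasked force components, and unmasked Hessian elements respectively
(n_F = 3 * sum_i n_atoms(i); n_H = sum_i (3 n_atoms(i))^2 — the full
symmetric matrix, both halves counted).  Default weights eta_F = 0.08,
eta_H = 0.02; :func:`calibrate_weights` re-derives them for a dataset as
the factors that would make the final force and Hessian RMSEs of an
equal-weight fit match its final energy RMSE.

Setting (eta_F, eta_H) = (0, 0) trains an E model, eta_F > 0 = eta_H an
E-F model, and both positive an E-F-H model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .derivatives import DerivativeBundle
from .descriptor import AEVSpec
from .model import (ArchConfig, Ensemble, FeaturizedBatch, PotentialModel,
                    featurize_structures)
from .nn import Adam, mlp_jet_backward
from .structures import PaddedBatch, mask_counts


class TrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# loss definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossWeights:
    """Dimensionless weights of the force and Hessian loss terms."""

    eta_f: float = 0.08
    eta_h: float = 0.02

    def __post_init__(self):
        if self.eta_f < 0 or self.eta_h < 0:
            raise TrainingError("loss weights must be non-negative")

    @property
    def variant(self) -> str:
        if self.eta_h > 0:
            return "E-F-H" if self.eta_f > 0 else "E-H"
        return "E-F" if self.eta_f > 0 else "E"

    @classmethod
    def e_model(cls):
        return cls(0.0, 0.0)

    @classmethod
    def ef_model(cls, eta_f: float = 0.08):
        return cls(eta_f, 0.0)

    @classmethod
    def efh_model(cls, eta_f: float = 0.08, eta_h: float = 0.02):
        return cls(eta_f, eta_h)


def loss_terms(pred: DerivativeBundle, ref: PaddedBatch):
    """(eps_E, eps_F, eps_H) masked RMSEs between prediction and reference.

    Terms whose prediction or label is absent are returned as None; sums
    run over unmasked elements only.
    """
    if pred.atom_mask.shape != ref.atom_mask.shape or \
            not np.array_equal(pred.atom_mask, ref.atom_mask):
        raise TrainingError("prediction/reference masks differ")
    M, n_f, n_h = mask_counts(ref)
    eps_e = eps_f = eps_h = None
    if ref.energies is not None:
        eps_e = float(np.sqrt(((ref.energies - pred.energies) ** 2).sum() / M))
    if ref.forces is not None and pred.forces is not None:
        mask3 = ref.atom_mask[..., None]
        r = (ref.forces - pred.forces) * mask3
        eps_f = float(np.sqrt((r ** 2).sum() / n_f))
    if ref.hessians is not None and pred.hessians is not None:
        cm = ref.coord_mask
        w = cm[:, :, None] * cm[:, None, :]
        r = (ref.hessians - pred.hessians) * w
        eps_h = float(np.sqrt((r ** 2).sum() / n_h))
    return eps_e, eps_f, eps_h


def total_loss(terms, weights: LossWeights) -> float:
    """Weighted sum eps_E + eta_F eps_F + eta_H eps_H."""
    eps_e, eps_f, eps_h = terms
    out = eps_e
    if weights.eta_f > 0:
        if eps_f is None:
            raise TrainingError("eta_F > 0 but no force term available")
        out += weights.eta_f * eps_f
    if weights.eta_h > 0:
        if eps_h is None:
            raise TrainingError("eta_H > 0 but no Hessian term available")
        out += weights.eta_h * eps_h
    return float(out)


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Per-epoch loss history plus final masked RMSEs of one training run."""

    history: pd.DataFrame
    final_train: dict
    final_val: dict
    seed: int
    weights: LossWeights
    n_train: int
    n_val: int
    data_fraction: float = 1.0
    wall_time_s: float = 0.0   # informational only

    @property
    def finals(self) -> dict:
        """Final RMSEs on the validation split (train split if no val)."""
        return self.final_val if self.n_val > 0 else self.final_train


def calibrate_weights(initial_fit) -> LossWeights:
    """Weights that balance force/Hessian RMSEs against the energy RMSE.

    Given a fit (or an (eps_E, eps_F, eps_H) triple) obtained with
    eta_F = eta_H = 1, returns eta_F = eps_E/eps_F and eta_H = eps_E/eps_H.
    """
    if isinstance(initial_fit, FitReport):
        f = initial_fit.finals
        eps = (f["energy_rmse"], f.get("force_rmse"), f.get("hessian_rmse"))
    else:
        eps = tuple(initial_fit)
    eps_e, eps_f, eps_h = eps
    if not eps_f or not eps_h:
        raise TrainingError("calibration needs nonzero force and Hessian RMSEs")
    return LossWeights(eps_e / eps_f, eps_e / eps_h)


# ---------------------------------------------------------------------------
# training configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (all seeded, all declared)."""

    hidden: tuple[int, ...] = (64, 64)
    lr: float = 5e-3
    epochs: int = 400
    batch_size: Optional[int] = None      # None = full batch
    val_fraction: float = 0.1             # split by molecule
    seed: int = 0
    lr_decay: float = 0.5
    patience: int = 40                    # epochs without improvement -> decay
    min_lr: float = 1e-5
    precision: str = "float32"            # training arithmetic; model is
                                          # cast back to float64 afterwards


def _required_order(weights: LossWeights) -> int:
    if weights.eta_h > 0:
        return 2
    if weights.eta_f > 0:
        return 1
    return 0


def _as_featurized(dataset, spec: AEVSpec, order: int) -> FeaturizedBatch:
    if isinstance(dataset, FeaturizedBatch):
        if dataset.order < order:
            raise TrainingError(
                f"featurized dataset has derivative order {dataset.order}, "
                f"the loss needs {order}")
        return dataset
    structures = dataset.structures if hasattr(dataset, "structures") else list(dataset)
    return featurize_structures(structures, spec, order)


def _check_labels(fb: FeaturizedBatch, weights: LossWeights) -> None:
    if fb.energies is None:
        raise TrainingError("dataset has no energy labels")
    if weights.eta_f > 0 and fb.forces_flat is None:
        raise TrainingError("eta_F > 0 but dataset has no force labels")
    if weights.eta_h > 0 and fb.hessians is None:
        raise TrainingError("eta_H > 0 but dataset has no Hessian labels")


def _counts(fb: FeaturizedBatch):
    M = fb.n_mol
    n_f = int(3 * fb.n_atoms.sum())
    n_h = int(((3 * fb.n_atoms) ** 2).sum())
    return M, n_f, n_h


def _loss_and_grads(model: PotentialModel, fb: FeaturizedBatch,
                    weights: LossWeights, order: int, want_grads: bool = True):
    """Loss terms and (optionally) parameter gradients on one batch."""
    E, dE, d2E, caches = model.forward(fb, order=order, with_cache=True)
    M, n_f, n_h = _counts(fb)
    res_e = E - fb.energies
    eps_e = math.sqrt(float(res_e @ res_e) / M)
    eps_f = eps_h = None
    dLdE = dLd_dE = dLd_d2E = None
    if want_grads:
        dLdE = res_e / (M * eps_e) if eps_e > 0 else np.zeros(M)
    if order >= 1 and fb.forces_flat is not None:
        F_pred = -dE
        rf = F_pred - fb.forces_flat
        eps_f = math.sqrt(float((rf * rf).sum()) / n_f)
        if want_grads and weights.eta_f > 0 and eps_f > 0:
            dLd_dE = -weights.eta_f * rf / (n_f * eps_f)
    if order >= 2 and fb.hessians is not None:
        rh = d2E - fb.hessians
        eps_h = math.sqrt(float((rh * rh).sum()) / n_h)
        if want_grads and weights.eta_h > 0 and eps_h > 0:
            dLd_d2E = weights.eta_h * rh / (n_h * eps_h)
    if not want_grads:
        return (eps_e, eps_f, eps_h), None
    # keep backward GEMMs in the batch's dtype (float32 training path)
    dt = next(iter(fb.element_rows.values()))[1].dtype
    grads = {}
    for e, (mi, cache) in caches.items():
        df = dLdE[mi].astype(dt, copy=False)
        dfg = None if dLd_dE is None else dLd_dE[mi].astype(dt, copy=False)
        dfh = None if dLd_d2E is None else dLd_d2E[mi].astype(dt, copy=False)
        grads[e] = mlp_jet_backward(model.params[e], cache, df, dfg, dfh)
    return (eps_e, eps_f, eps_h), grads


def _cast_model(model: PotentialModel, dtype) -> None:
    model.params = {e: [(W.astype(dtype), b.astype(dtype)) for W, b in ps]
                    for e, ps in model.params.items()}
    model.feat_shift = {e: v.astype(dtype) for e, v in model.feat_shift.items()}
    model.feat_scale = {e: v.astype(dtype) for e, v in model.feat_scale.items()}


def fit(dataset, weights: LossWeights, config: TrainConfig,
        spec: Optional[AEVSpec] = None) -> tuple[PotentialModel, FitReport]:
    """Train one model; deterministic given (config.seed, data order).

    ``dataset`` may be a structure sequence, an RTP dataset, or a
    pre-featurized batch (reused across fits — descriptor derivatives do
    not depend on weights).  Returns the best-validation checkpoint.
    """
    import time as _time
    t0 = _time.time()
    if spec is None:
        spec = dataset.spec if isinstance(dataset, FeaturizedBatch) else AEVSpec()
    order = _required_order(weights)
    fb_all = _as_featurized(dataset, spec, order)
    _check_labels(fb_all, weights)

    ss = np.random.SeedSequence([int(config.seed), 0x484650])
    split_rng, init_seed = np.random.default_rng(ss.spawn(1)[0]), ss.spawn(2)[1]
    M = fb_all.n_mol
    n_val = int(round(config.val_fraction * M))
    n_val = min(n_val, M - 1)
    perm = split_rng.permutation(M)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    fb_train = fb_all.subset(train_idx) if n_val > 0 else fb_all
    fb_val = fb_all.subset(val_idx) if n_val > 0 else None
    dtype = np.dtype(config.precision)
    if dtype != np.float64:
        fb_train = fb_train.astype(dtype)
        if fb_val is not None:
            fb_val = fb_val.astype(dtype)

    model = PotentialModel.initialize(
        ArchConfig(hidden=tuple(config.hidden), aev_spec=spec), init_seed)

    # per-element reference energies: least squares on element counts
    counts = fb_train.element_counts.astype(float)
    ref, *_ = np.linalg.lstsq(counts, fb_train.energies, rcond=None)
    for k, e in enumerate(spec.elements):
        model.ref_energies[e] = float(ref[k])

    # feature standardization from the training split
    for e, (mi, G, _, _) in fb_train.element_rows.items():
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        model.feat_shift[e] = mu
        model.feat_scale[e] = np.where(sd > 1e-6, sd, 1.0)
    if dtype != np.float64:
        _cast_model(model, dtype)

    flat_params = [a for e in model.params for Wb in model.params[e] for a in Wb]
    opt = Adam(flat_params, lr=config.lr)

    if config.batch_size is None or config.batch_size >= fb_train.n_mol:
        batches = [fb_train]
    else:
        brng = np.random.default_rng(ss.spawn(3)[2])
        order_idx = brng.permutation(fb_train.n_mol)
        batches = [fb_train.subset(order_idx[i:i + config.batch_size])
                   for i in range(0, fb_train.n_mol, config.batch_size)]

    history = {"epoch": [], "lr": [], "train_loss": [], "val_loss": [],
               "eps_e": [], "eps_f": [], "eps_h": []}
    best_loss = np.inf
    best_params = None
    stall = 0
    lr = config.lr
    for epoch in range(config.epochs):
        terms_acc = []
        for fb in batches:
            terms, grads = _loss_and_grads(model, fb, weights, order)
            flat_grads = []
            for e in model.params:
                if e in grads:
                    for dW, db in grads[e]:
                        flat_grads.extend((dW, db))
                else:
                    for W, b in model.params[e]:
                        flat_grads.extend((np.zeros_like(W), np.zeros_like(b)))
            opt.step(flat_params, flat_grads)
            terms_acc.append(terms)
        tm = terms_acc[-1]
        train_loss = total_loss(tm_safe(tm, weights), weights)
        if fb_val is not None:
            vterms, _ = _loss_and_grads(model, fb_val, weights, order,
                                        want_grads=False)
            monitor = total_loss(tm_safe(vterms, weights), weights)
        else:
            monitor = train_loss
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(monitor if fb_val is not None else np.nan)
        history["eps_e"].append(tm[0])
        history["eps_f"].append(tm[1])
        history["eps_h"].append(tm[2])
        if monitor < best_loss - 1e-12:
            best_loss = monitor
            best_params = {e: [(W.copy(), b.copy()) for W, b in ps]
                           for e, ps in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                lr *= config.lr_decay
                opt.lr = lr
                stall = 0
                if lr < config.min_lr:
                    break
    if best_params is not None:
        model.params = best_params

    final_train = _final_metrics(model, fb_train, order)
    if dtype != np.float64:
        _cast_model(model, np.float64)
    final_val = _final_metrics(model, fb_val, order) if fb_val is not None else {}
    model.provenance.update({
        "weights": (weights.eta_f, weights.eta_h),
        "seed": int(config.seed),
        "n_train": int(fb_train.n_mol),
        "epochs_run": len(history["epoch"]),
    })
    report = FitReport(pd.DataFrame(history), final_train, final_val,
                       seed=int(config.seed), weights=weights,
                       n_train=int(fb_train.n_mol), n_val=int(n_val),
                       wall_time_s=_time.time() - t0)
    return model, report


def tm_safe(terms, weights: LossWeights):
    """Restrict loss terms to the ones the weights actually use."""
    eps_e, eps_f, eps_h = terms
    return (eps_e,
            eps_f if weights.eta_f > 0 else None,
            eps_h if weights.eta_h > 0 else None)


def _final_metrics(model, fb, order) -> dict:
    terms, _ = _loss_and_grads(model, fb, LossWeights(0.0, 0.0), order,
                               want_grads=False)
    out = {"energy_rmse": terms[0]}
    if terms[1] is not None:
        out["force_rmse"] = terms[1]
    if terms[2] is not None:
        out["hessian_rmse"] = terms[2]
    return out


# ---------------------------------------------------------------------------
# ensemble training and evaluation
# ---------------------------------------------------------------------------

def fit_ensemble(dataset, weights: LossWeights, config: TrainConfig,
                 n_members: int, spec: Optional[AEVSpec] = None
                 ) -> tuple[Ensemble, list[FitReport]]:
    """Train ``n_members`` replicas differing only by their seed."""
    members, reports = [], []
    for i in range(n_members):
        cfg = replace(config, seed=int(np.random.SeedSequence(
            [int(config.seed), 7919 + i]).generate_state(1)[0] % (2 ** 31)))
        m, r = fit(dataset, weights, cfg, spec=spec)
        members.append(m)
        reports.append(r)
    return Ensemble(members, [r.seed for r in reports]), reports


@dataclass
class EvaluationReport:
    """Masked RMSEs per ensemble member, with mean +- sample std."""

    per_member: pd.DataFrame
    mean: dict
    std: dict


def evaluate_rmse(model_or_ensemble, dataset,
                  order: int = 2) -> EvaluationReport:
    """Energy/force/Hessian RMSEs, reported as mean +- std over members."""
    members = (model_or_ensemble.members
               if isinstance(model_or_ensemble, Ensemble)
               else [model_or_ensemble])
    spec = members[0].spec
    fb = _as_featurized(dataset, spec, order)
    rows = []
    for i, m in enumerate(members):
        terms, _ = _loss_and_grads(m, fb, LossWeights(1.0, 1.0), order,
                                   want_grads=False)
        row = {"member": i, "energy_rmse": terms[0]}
        if terms[1] is not None:
            row["force_rmse"] = terms[1]
        if terms[2] is not None:
            row["hessian_rmse"] = terms[2]
        rows.append(row)
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c != "member"]
    mean = {c: float(df[c].mean()) for c in metrics}
    std = ({c: float(df[c].std(ddof=1)) for c in metrics}
           if len(members) > 1 else {c: 0.0 for c in metrics})
    return EvaluationReport(df, mean, std)


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

def learning_curve(dataset, fractions: Sequence[float],
                   loss_variants: Sequence[LossWeights],
                   seed: int, test_set, config: TrainConfig,
                   spec: Optional[AEVSpec] = None) -> pd.DataFrame:
    """RMSE on a fixed held-out set versus training-data fraction.

    Subsets are nested: the molecules used at a smaller fraction are a
    subset of those used at any larger fraction.
    """
    if spec is None:
        spec = dataset.spec if isinstance(dataset, FeaturizedBatch) else AEVSpec()
    max_order = max(_required_order(w) for w in loss_variants)
    fb = _as_featurized(dataset, spec, max_order)
    fb_test = _as_featurized(test_set, spec, 2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4c43]))
    perm = rng.permutation(fb.n_mol)
    rows = []
    for frac in sorted(fractions):
        if not 0 < frac <= 1:
            raise TrainingError(f"fraction {frac} outside (0, 1]")
        k = int(round(frac * fb.n_mol))
        if k < 1:
            raise TrainingError(f"fraction {frac} yields no molecules")
        sub = fb.subset(perm[:k])
        for w in loss_variants:
            model, _rep = fit(sub, w, replace(config, seed=seed), spec=spec)
            ev = evaluate_rmse(model, fb_test)
            rows.append({"fraction": frac, "n_train": k, "variant": w.variant,
                         **ev.mean})
    return pd.DataFrame(rows)
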