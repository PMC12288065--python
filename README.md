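# hesspot

Neural-network interatomic potentials trained on energies, forces, **and
full 3N×3N Hessians**, together with the evaluation protocols that make
curvature training measurable — off-path accuracy, molecular-dynamics
stability ramps, climbing-image NEB barriers, and vibrational spectra —
all exercised on analytic reference surfaces with exact labels.

## Who this is for

Researchers developing machine-learned interatomic potentials (MLIPs)
for reactive chemistry, where training data are critical points of the
potential-energy surface (reactants, transition states, products) and
the question is how much second-derivative information buys in
extrapolation away from them. Because the reference surfaces here are
analytic (Morse bond networks with double-well bending terms, the
quartic double well, Müller–Brown), every energy, force, and Hessian
label is exact and every benchmark has a closed-form or
independently computed answer.

## The model and loss

The potential is a high-dimensional neural network of the
Behler–Parrinello/ANI form: atomic environment vectors (radial and
angular symmetry functions, C² cutoff) feed per-element feed-forward
networks whose outputs sum to the molecular energy. Forces and Hessians
of the prediction are exact chain-rule derivatives, obtained by
propagating second-order jets (value, gradient, Hessian triples) through
descriptor and network. The training loss is

    L = ε_E + η_F·ε_F + η_H·ε_H,

with ε_E, ε_F, ε_H the masked RMSEs of energies, force components, and
Hessian elements, and default weights η_F = 0.08, η_H = 0.02
(re-derivable per dataset with `calibrate_weights`). The choice
(η_F, η_H) = (0,0) / (0.08, 0) / (0.08, 0.02) defines the E, E–F, and
E–F–H model families that the benchmarks compare.

See `docs/methods.md` for the full model, unit system, sampling rules,
and study conditions.

## Worked example

Train an E–F–H model on a synthetic reaction dataset and compare its
off-path Hessian error with a force-only fit:

```python
import numpy as np
from hesspot import (TriatomicFamily, build_rtp_dataset, featurize_structures,
                     LossWeights, TrainConfig, fit, evaluate_rmse)
from hesspot.benchmarks import benchmark_descriptor_spec

spec = benchmark_descriptor_spec()
data = build_rtp_dataset(TriatomicFamily(), n_reactions=40, seed=11)
fb = featurize_structures(data.structures, spec, order=2)

cfg = TrainConfig(hidden=(24, 24), lr=1e-2, epochs=700, seed=0,
                  patience=60, val_fraction=0.0)
efh, _ = fit(fb, LossWeights(0.08, 0.02), cfg, spec=spec)
ef,  _ = fit(fb, LossWeights(0.08, 0.00), cfg, spec=spec)

print(evaluate_rmse(efh, fb).mean)
print(evaluate_rmse(ef,  fb).mean)
```

prints (training-set RMSEs, kcal/mol, kcal/(mol·Å), kcal/(mol·Å²)):

```
{'energy_rmse': 0.0110..., 'force_rmse': 0.0212..., 'hessian_rmse': 0.509...}
{'energy_rmse': 0.0011..., 'force_rmse': 0.0018..., 'hessian_rmse': 284.37...}
```

Both variants fit energies and forces; only the Hessian-trained model
learns the curvature (0.51 vs 284 against a label RMS of ≈ 283). The
off-path story — E–F–H < E–F < E on normal-mode-sampled test structures,
a ≥2× Hessian-RMSE gap, higher MD failure temperatures, and convergent
NEB barriers — is what `scripts/acceptance.py` measures.

A command-line interface mirrors the library
(`hesspot generate-data / train / evaluate / nms-sample / md-ramp /
neb-run / vib-spectrum`), each writing a self-describing run directory.

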