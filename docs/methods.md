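# Methods

## The model

`hesspot` implements high-dimensional neural-network interatomic
potentials of the Behler–Parrinello/ANI lineage. A molecule's energy is a
sum of atomic contributions,

    E(x, Z) = Σ_a  f_{Z_a}( G_a(x) )  +  Σ_a  E_ref(Z_a),

where `G_a` is the atomic environment vector (AEV) of atom `a` — radial
and angular symmetry functions of its neighbourhood —

    radial:   Σ_j exp(-η_r (r_ij - R_s)²) f_c(r_ij)
    angular:  2^(1-ζ) Σ_{j<k} (1 + cos(θ_ijk - θ_s))^ζ
              · exp(-η_a ((r_ij + r_ik)/2 - R_s)²) f_c(r_ij) f_c(r_ik)

and `f_{Z}` is a per-element feed-forward network. The reference energies
`E_ref(Z)` are fitted by least squares on element counts before network
training (standard self-energy removal; it conditions the regression
target and leaves the networks to learn the interaction energy).

The distinguishing feature is training on *second derivatives*. The loss

    L = ε_E + η_F ε_F + η_H ε_H

combines the RMSE of molecular energies (ε_E, over the M molecules of a
batch), force components (ε_F, over n_F = 3 Σ n_atoms unmasked
components), and Hessian elements (ε_H, over n_H = Σ (3 n_atoms)²
elements — the full symmetric matrix, both halves counted). Setting
(η_F, η_H) = (0, 0) trains an E model, η_F > 0 only an E–F model, both
positive an E–F–H model. Defaults are η_F = 0.08 and η_H = 0.02;
`calibrate_weights` re-derives them for any dataset as the ratios that
would make the final force and Hessian RMSEs of an equal-weight fit equal
its final energy RMSE.

## Nested differentiation

Forces are the negative gradient of the predicted energy; Hessians its
second derivative. Both are computed analytically (no finite differences
anywhere in the prediction or training path) by *second-order jet
propagation*: every intermediate quantity carries its value, gradient,
and Hessian with respect to the Cartesian coordinates, and every
operation (descriptor algebra, linear layers, activations) maps jets to
jets by the chain rule. For a hidden layer `h = tanh(Wg + b)`:

    value     t      = tanh(a)
    gradient  ∇h     = φ'(a) ∇a
    Hessian   ∇²h    = φ'(a) ∇²a + φ''(a) ∇a ⊗ ∇a

Training on forces and Hessians requires the gradient of these
*derivatives* with respect to the weights — a third-order mixed
derivative. The reverse pass through the jet pipeline is derived by hand
(it needs φ''' as well) and is verified against finite differences of the
total loss in the test suite. Because the descriptor jets do not depend
on the weights, they are computed once per dataset and reused across all
fits, which is what makes ensemble studies affordable on one CPU.

Two smoothness constraints follow from differentiating twice:

* the activation must be C² — tanh is used (the popular kinked/CELU-style
  activations have discontinuous second derivatives, which makes Hessian
  labels unlearnable);
* the cutoff function must be C² at R_c — the default is
  `(1 - (r/R_c)²)³`, whose second derivative vanishes at the cutoff;
  the conventional cosine cutoff (curvature jump at R_c) is retained as
  an option for lineage comparisons.

The angular function uses arccos with an epsilon clip near ±1; all
geometries generated by the package keep bond angles away from 0/π, so
the clip never activates in practice.

Training arithmetic runs in float32 (the loss gradient tolerates it; it
roughly halves time and memory); the returned model is cast back to
float64, so predictions and their derivative consistency are full
precision.

## Units and constants

Internal units are kcal/mol, Å, amu, fs everywhere; conversions (CODATA
2018) happen only at boundaries. The acceleration conversion factor
(kcal mol⁻¹ Å⁻¹ / amu → Å fs⁻²) is ≈ 4.184 × 10⁻⁴; mass-weighted Hessian
eigenvalues map to wavenumbers via ν̃ = sign(λ)·√(|λ|·4.184×10⁻⁴)/(2πc).

## Synthetic reference surfaces

No electronic-structure data is used anywhere. Ground truth comes from
analytic force fields whose energy, gradient, and Hessian are exact
(chain-rule, via the same jet engine):

* **Quartic double well** — V = c(x⁴ − 2x²) for a single particle
  (harmonic in y, z): minima at ±1 Å with V = −c, an exact barrier of c
  (default 1 kcal/mol). Used for NEB and IRC closed-form checks.
* **Müller–Brown** — the classic two-saddle 2-D surface (standard
  parameters, kcal/mol), harmonically confined in z. Used for multi-basin
  NEB/saddle-search cross-checks; no literature constants are asserted —
  the surface's own critical-point search is the oracle.
* **Morse bond networks** — molecules built from pairwise Morse bonds,
  bending terms expressed in q = cos θ, and a stretch–bend coupling term.

### The reaction family

The `TriatomicFamily` generates "reactions": bent terminal–center–terminal
molecules over a 5-element alphabet (H, C, N, O, S) whose bending
potential is a tilted quartic double well in q = cos θ, so each surface
has exactly two conformational minima joined by one first-order saddle
(reactant / transition state / product). Two design points matter:

1. **One consistent surface over compositions.** All force-field
   parameters are a fixed deterministic function of the element
   combination, drawn once from a "universe" seed: bond parameters depend
   on the (center, terminal) pair, bend parameters on the full triple.
   Reaction diversity comes from sampling distinct compositions
   (75 available). This mirrors how a single level of electronic-structure
   theory defines one PES over chemistry; without it, identical
   geometries would carry contradictory labels and the learning problem
   would be ill-posed.
2. **Stretch–bend coupling.** A term g·(Δr₁ + Δr₂)(q − q_mid) shifts the
   equilibrium bond lengths between the reactant, TS, and product, the
   way real conformers differ. Without it all three critical points of a
   reaction share identical bond lengths, and the dataset would carry no
   information about how stretch curvature varies along the reaction —
   exactly the third-order information off-path Hessian prediction needs.

Default parameter ranges (drawn per element combination): Morse depth
60–120 kcal/mol, width 1.6–2.4 Å⁻¹, r₀ 0.96–1.45 Å; bend wells at
85–110° and 135–160°, barrier 3–8 kcal/mol, tilt within ±20% of the
barrier, |g| 20–60 kcal mol⁻¹ Å⁻¹. These give bond stiffnesses,
barrier heights, and geometry changes in the range of small covalent
molecules.

Critical points are located by Newton eigenvector-following (trust
radius 0.1 Å·√n, rigid-body modes projected out, gradient tolerance
10⁻⁶ kcal mol⁻¹ Å⁻¹ for dataset generation — far tighter than
electronic-structure practice, affordable because labels are analytic).
IRC paths are fixed-step Euler steepest descent in mass-weighted
coordinates (step 0.01 amu^½ Å, seeded ±0.01 amu^½ Å along the negative
eigenvector), with adaptive step halving to enforce monotone descent, a
stall detector for the stiff terminal basins, and an exact local
minimization appended at each end.

### What the generator does and does not emulate

The family reproduces the *structure* of a reaction dataset — critical
points with exact E/F/H labels, IRC paths, thermally displaced off-path
geometries — with bond stiffness and barrier scales of small organic
molecules. It does not emulate bond breaking, charge transfer,
long-range interactions, conformational entropy, or label noise; passing
the benchmarks here demonstrates that Hessian-aware training extracts
curvature information as designed, not that any particular accuracy would
be reached on real quantum-chemistry data.

## Normal-mode sampling

Off-path structures are drawn by displacing along mass-weighted normal
modes with coefficients c_i = ±√(3 k_B T R / k_i), R ~ U(0,1) — each
sampled mode receives on average 3k_BT/4 of potential energy (the
NMS rule of the ANI data-generation lineage; the displacement law is a
declared choice, default 300 K). Three exclusions apply:

* rigid translations/rotations, identified by overlap with the
  mass-weighted rigid-body subspace — at non-stationary geometries these
  carry small nonzero eigenvalues, and sampling them as "soft modes"
  draws enormous unphysical displacements (finite steps along linearized
  rotations stretch bonds at second order);
* a designated reaction-coordinate mode (the IRC tangent at intermediate
  images, supplied per image by the IRC tracer), removed both by
  coefficient and by projection;
* modes below a stiffness floor, which also removes the transition
  state's imaginary mode (an inverted oscillator cannot be thermally
  sampled).

A 0.5 Å per-atom safety clip guards against unphysical overlaps.

## MD stability protocol

Langevin dynamics uses the BAOAB splitting (friction 0.01 fs⁻¹, time
step 0.5 fs). The iterative-heating protocol starts at 5 K and raises the
target by 5 K after every 5 ps stage until failure: a molecule fails as
soon as the mean distance of any monitored pair over the trailing 50
steps exceeds 1.5× — or falls below 0.75× — its equilibrium value at the
model-optimized geometry (strict inequalities, checked every step once 50
steps exist). Monitored pairs are the bonded pairs of the optimized
geometry (from the force-field topology when available, else a 1.3×
covalent-radii criterion); an all-pairs mode is available for the
close-contact reading. Velocities persist across temperature increments.
If the initial model-side geometry optimization itself distorts a bonded
pair past those thresholds, the run is recorded as failed on optimization
with zero simulated time.

The benchmark harness runs a scaled-down schedule — 25 K start, 25 K
increments, 0.5 ps stages, 300 K cap — so that a full E vs E–F–H
comparison over five molecules completes in minutes on one CPU; the
protocol object itself is schedule-agnostic.

## NEB

Climbing-image NEB with the energy-weighted upwind ("improved") tangent;
spring constant accepted in eV/Å² (default 50) and converted internally.
The optimizer is FIRE: NEB's projected forces are not the gradient of any
scalar objective, so a force-based minimizer is required (quasi-Newton
line-search methods assume a gradient). The climbing image — the current
maximum-energy inner image, re-selected each iteration after a short
plain-NEB phase — feels the inverted parallel true force and no springs.
Convergence is declared when the largest per-atom projected-force norm
falls below the threshold (default 0.05 eV/Å) *and* climbing is active;
non-convergence is reported in the returned path object, never raised.
Default 16 images.

## Vibrational analysis

Frequencies come from diagonalizing the mass-weighted Hessian
M^(−1/2) H M^(−1/2) directly, with *no* projection of translational or
rotational modes — every geometry yields all 3N modes, so model and
reference are compared on identical footing. Imaginary modes are encoded
as negative wavenumbers. Spectra along a path are sorted by magnitude per
geometry, with optional overlap-based mode tracking along paths; masses are isotopically averaged standard
atomic weights. No scaling factors are applied.

## Training procedure

Adam (full batch by default at these dataset sizes; fixed mini-batch
partitions when a batch size is set), learning-rate halving after a
patience window without improvement, stop below a floor learning rate,
best-monitored checkpoint returned. With a validation fraction > 0 the
monitor is the validation loss (split by molecule, seeded); the benchmark
protocols train with `val_fraction = 0` — at 40-reaction scale a held-out
critical point of one composition is effectively out of distribution, so
validation-based checkpointing would select a barely trained model, and
the protocols evaluate on separate test sets anyway. Feature
standardization (per element, training split) is folded into the model.
Everything is reproducible from a single seed.

## Benchmark study conditions

Scaled for a single CPU; sizes are the package's own study conditions:

* **Trend** — 40 reactions (120 structures) of the triatomic family;
  descriptor with 5 radial shifts and 3×1 angular shifts (L = 70);
  networks 2×24; five independently seeded fits per loss variant
  (E: 500 epochs, E–F: 500, E–F–H: 700 — the Hessian term converges more
  slowly). The off-path test set combines NMS around the critical points
  of 10 reactions (all thermal modes at the minima) and around four
  intermediate IRC images per reaction (path tangent excluded), ~170
  structures. Reported: median per-fit energy/Hessian RMSE per variant.
* **Single-TS** — one composition's TS, ensembles of 4 per variant,
  evaluated by the ensemble-mean |energy error| over IRC images within
  ±0.25 amu^½ Å of the TS.
* **MD stability** — first five reactants of the trend dataset, one ramp
  per (molecule, model), E vs E–F–H vs exact-FF control.

## Known limitations

* Molecules are small (the protocols use triatomics); batch Hessians are
  dense (M, 3N, 3N), so scaling beyond tens of atoms needs the
  row-block-wise evaluation path and smaller batches.
* The E–F vs E energy gap off-path is carried by near-critical-point
  samples (where force training pins the slopes); far from all training
  data both degrade equally, consistent with the models having no
  information there.
* The quoted full MD protocol (5 K steps, 5 ps stages to 2500 K) is
  supported but takes hours per molecule in pure numpy; the benchmark
  schedule is the scaled version above.
* No periodic systems, charges, spin, or dispersion.
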