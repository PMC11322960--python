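# Methods

`graphff` learns the parameters of a Class I molecular-mechanics (MM) force
field directly from conformer energies, forces, and target partial charges,
replacing discrete atom-typing rules with a continuous, learned map from a
chemical graph to parameters. This note records the model, the training
procedure, the synthetic data generator, the evaluation conventions, and the
numerical choices, together with the reasoning behind the genuinely open
design decisions.

## Potential energy model

For coordinates x (Å) and parameters Φ the potential (kcal/mol) is

    U(x; Φ) = Σ_bonds   1/2 K_r (r − r0)²
            + Σ_angles  1/2 K_θ (θ − θ0)²
            + Σ_propers Σ_{n=1..6} K_{φ,n} (1 + cos n φ)
            + Σ_impropers Σ_{n=1,2} K_{ψ,n} (1 + cos n ψ)   (3-fold trefoil)
            + Σ_pairs   4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶]
            + Σ_pairs   k_e q_i q_j / r

Conventions that differ between MM codes and are therefore fixed here
explicitly:

* **Harmonic 1/2 K (x − x0)²** — AMBER-style tables fold the 1/2 into K;
  the synthetic reference force field and the model use the same convention,
  so no conversion is ever needed inside the package.
* **Torsion phases are 0 for every periodicity** and amplitudes are
  sign-unconstrained; a negative amplitude is equivalent to a phase of π,
  so the usual phase freedom is preserved without learning angles. Proper
  torsions carry periodicities n = 1..6, impropers n = 1, 2.
* **Improper torsions** exist at every atom with exactly three bonded
  neighbors, regardless of hybridization: the model can learn near-zero
  amplitudes where planarity is not enforced, which avoids a hand-written
  hybridization rule. Geometrically an improper with central atom c and
  outer atoms (a, b, d) is the sum over the three cyclic outer arrangements
  of the ordinary dihedral on (outer1, c, outer2, outer3); the same
  amplitudes apply to all three terms, and the pooled representation is
  exactly invariant under the cyclic relabeling.
* **Nonbonded**: Lorentz–Berthelot combination (arithmetic σ, geometric ε),
  gas-phase all-pairs evaluation without cutoffs, 1-2 and 1-3 pairs
  excluded, 1-4 pairs scaled (electrostatics 1/1.2, Lennard-Jones 0.5;
  configurable). Ring-closure ambiguities use the shortest bond path.
  Coulomb constant 332.0637 kcal·mol⁻¹·Å·e⁻². Dihedral angles use the
  IUPAC sign convention via atan2, range (−π, π].

## Parametrization network

**Stage 1 — atom embeddings.** Node features are strictly
resonance-invariant: element one-hot over {H, C, N, O, S, P, F, Cl, Br, I},
heavy-atom degree one-hot (0-4), total hydrogen count one-hot (0-4), and
ring-membership flags for ring sizes 3-8 (RDKit ring perception; plain
message passing cannot perceive ring sizes, so this is supplied as input).
Formal charges and aromaticity flags are deliberately excluded — both change
between resonance forms of one molecule, and chemically equivalent inputs
must receive identical parameters. The molecular net charge enters only the
charge-equilibration constraint. Three message-passing layers (sum
aggregation over bonded neighbors, ReLU, width 128 by default) produce
latent atom vectors; the final per-atom embedding is the raw feature vector
concatenated with the message-passing output. This skip connection keeps
the local atom identity directly visible to every readout — without it the
readouts must recover the identity through the trained trunk, which in
practice delays symmetry breaking between chemical environments by
thousands of optimization steps.

**Stage 2 — symmetry-preserving term embeddings.** A term's feature vector
is the sum of a per-class feed-forward network over the physically
equivalent orderings of its atom tuple (Janossy pooling): both orientations
for bonds, angles, and proper torsions; the three cyclic outer arrangements
(central atom fixed first) for impropers. Invariance under these
permutations is therefore exact by construction, to machine precision, for
any weights. The pooling, readout, and charge-head perceptrons use a leaky
rectifier (negative-side slope 0.01): the first few epochs of training see
very large transient gradients, and a hard rectifier lets head units die
irreversibly, which in some initializations froze the directly supervised
charge head near a constant predictor.

**Stage 3 — readout maps.** Each class has its own two-layer network. The
harmonic classes emit the *natural coordinates* (K, K·x0) through scaled
softplus units rather than (K, x0):

    K_r  = 400·softplus(a) + 10⁻³        K_r·r0 = 520·softplus(b)
    K_θ  = 100·softplus(c) + 10⁻³        K_θ·θ0 = 160·softplus(d)

with r0 and θ0 recovered as ratios (θ0 additionally passed through a
sigmoid that is ≈identity over 1.5-2.3 rad but pins the value inside
(0, π)). The reason is the shape of the fitting landscape: in (K, x0)
coordinates a wrong equilibrium value makes K → 0 optimal, and K → 0 in
turn removes all gradient from x0 — a self-locking saddle that gradient
optimizers do not escape (we observed exactly this collapse). In
(K, K·x0) coordinates the energy 1/2 K x² − (K x0)x + const is linear in
both outputs (the constant is invisible after per-molecule centering), both
gradients stay alive everywhere, and positivity of the two softplus outputs
still guarantees K > 0 and x0 > 0. Torsion amplitudes are linear outputs.
Final-layer biases are initialized so an untrained network emits physical
priors (K_r ≈ 400 kcal/mol/Å², r0 ≈ 1.3 Å, K_θ ≈ 80 kcal/mol/rad²,
θ0 ≈ 2.0 rad, torsions 0), with small (σ = 0.01) final-layer weights.

**Lennard-Jones parameters are never learned**: σ and ε are copied from a
reference nonbonded table keyed by the reference force field's own atom
typing, mirroring the practice of refitting valence terms and charges while
transferring LJ from an established force field.

## Partial charges

A per-atom head predicts electronegativity e_i = 50·(raw) kcal/mol/e and
hardness s_i = 50·softplus(raw) + 1 kcal/mol/e² (strictly positive).
Charges minimize Σ_i (e_i q_i + s_i q_i²) subject to Σ q_i = Q, solved in
closed form with the Lagrange multiplier

    λ = (Q + Σ e_i/2s_i) / Σ 1/2s_i,     q_i = (λ − e_i)/2s_i,

so the total charge is conserved exactly (to ≤1e−12 e in floating point)
for every molecule, including ions. The hardness convention (s q² versus
1/2 s q²) only rescales the learned s and is observationally equivalent
after training; the s q² form is fixed here. Charges are geometry
independent; no post-hoc correction is applied. Target charges are an
input per molecule (arrays in canonical atom order keyed by canonical
SMILES); the package never computes semi-empirical charges itself.

## Training

The loss over a batch of molecules is

    L = w_E · MSE(centered U_MM, centered U_ref)          [per conformer]
      + w_F · MSE(F_MM, −∇U_ref)                          [per component]
      + w_q · MSE(q, q_target)                            [per atom]
      + λ   · (Σ K_{φ,n}² + Σ K_{ψ,n}²)

Energies are centered to zero mean per molecule — the same linear operator
applied to both series — because an MM functional form cannot represent
per-molecule formation-energy offsets; forces compare against the *negative*
of the stored reference gradients (sign convention unit-tested). Library
defaults are w_E = w_F = w_q = 1 and λ = 0.01. Optimization is full-batch
Adam; with geometry factors (distances, angles, dihedrals, and their exact
Cartesian gradients) precomputed once per conformer set, an epoch reduces to
a network forward/backward plus tensor contractions, and the entire
gradient — including the force-matching term, i.e. ∂²U/∂x∂Φ chained through
the network — is evaluated analytically in NumPy. Gradient correctness is
verified against finite differences of the complete loss in the test suite.

Datasets are split by molecule (canonical isomeric SMILES) into train,
validation, and test sets at 80:10:10 with a seeded shuffle; conformers of
one molecule never straddle splits, and per-identity overrides support
asymmetric (train-only / test-only) designs. Training is exactly
reproducible from the seed: initialization is the only stochastic element
and full-batch updates have no sampling noise.

## Synthetic data generator

Ground truth is a hand-specified *MM reference force field*, not quantum
chemistry. This is deliberate: recovery error then measures the learning
pipeline alone, because a perfect model can reproduce the generating
surface exactly. The reference typing maps each atom to
(element, heavy degree, H count, any-ring flag) — deliberately *coarser*
than the node features, so every ground-truth assignment is resolvable by
the network. Per-type parameters are generated once by hashing the type key
into a seeded generator (assignments are independent of which molecules are
parametrized, and identical across runs), inside physical ranges: bond
K ∈ [300, 700] kcal/mol/Å² with r0 from covalent-radius sums ±0.04 Å; angle
K ∈ [60, 140] kcal/mol/rad² with θ0 from the central atom's coordination
(≈109.5°/118°/110° ± 3°); torsion amplitudes up to ±1.2 kcal/mol for
n ≤ 3 keyed by the central bond's type pair; improper amplitudes with a
planarizing n = 2 component keyed by the central type; element-based σ, ε,
and base charges with per-type jitter. Per-molecule target charges are the
per-type base charges shifted uniformly so they sum exactly to the net
charge — a distribution the equilibration model can represent exactly.

The default fixture set holds 28 molecules in homolog pairs spanning
alkanes, cycloalkanes, alkenes and dienes, arenes, phenols, pyridines,
pyrrole, furan, alcohols, an ether, amines, aldehydes, ketones, and charged
species (two carboxylates at −1, two alkylammonium ions at +1), with 30
conformers per molecule by default (range 25-100 supported). Conformers
come from a random-walk Metropolis chain at a 500 K acceptance temperature
(Cartesian displacements of σ = 0.012 Å per coordinate plus rotatable-bond
torsion moves of σ = 0.5 rad every third step, thinned every 15 steps)
started from the relaxed geometry, whose equilibrium potential energy is
≈ (3N−6)/2 · kT above the minimum — guaranteeing a substantial high-energy
population. The first stored conformer is the relaxed structure itself, and
generation is extended until every molecule has an energy spread above
1 kcal/mol with at least 10% of conformers ≥ 3 kcal/mol above its minimum.
Stored energies and gradients are computed by `oracle_energy`, a
deliberately simple loop-based implementation with independently derived
analytic gradients (angle gradients through d cosθ, dihedral gradients
through product-rule differentiation of the atan2 arguments) that shares no
energy code with the vectorized potential and doubles as its cross-check.

What the generator does *not* emulate: quantum-chemical anharmonicity,
coupling terms, charge-flow/polarization, conformer-dependent charges, or
the chemical breadth of real training corpora. Passing the recovery test
therefore demonstrates that the pipeline — graph featurization, pooled
symmetry-preserving representations, readouts, charge equilibration, the
differentiable potential, and the optimizer — can identify a Class I
surface from energies, forces, and charges; it does not certify accuracy
against real quantum chemistry.

## The parameter-recovery experiment

`graphff.fitting.parameter_recovery(seed)` builds the fixture set, splits
it 80:10:10 by molecule, trains on the train split, and evaluates the
learned surface on **freshly sampled conformers of the fitted molecules** —
geometries the optimizer has never seen (10 per molecule, new Metropolis
chains). Because assigned parameters are conformer-independent, this is
the well-posed test of whether the generating surface was recovered rather
than memorized pointwise.

Training uses an *amortized* strategy that exploits the structure of the
problem, in three phases:

1. **Per-molecule linear surface fits.** With charges fixed at their
   targets (exact in the synthetic setting) and Lennard-Jones transferred,
   the centered conformer energies and all force components are *linear*
   in the valence unknowns — bonds and angles in their natural (K, K·x0)
   coordinates (the leftover P²/2K constants are conformer-independent and
   vanish under centering) and the torsion amplitudes directly. Each
   molecule's valence parameters are therefore obtained by a
   ridge-regularized linear least squares over its own conformers
   (regularized toward physical priors in scaled coordinates, so
   directions the conformer set does not determine stay at the priors).
   This step is deterministic, takes seconds, and reproduces each
   training surface essentially exactly; the validity of the design
   matrix is pinned by the test suite (zero residual at the generating
   parameters).
2. **Network amortization.** The network is trained by plain supervised
   regression in raw-output space onto the per-molecule fits (the output
   maps are inverted analytically for the targets, including the θ0
   squash; charge-head targets realize the target charges through
   equilibration with uniform hardness). ~2500 full-batch Adam epochs.
3. **End-to-end fine-tune.** A short run of the standard
   energy/force/charge loss (w_q = 100, λ = 5e-4, lr 3e-4 with decay,
   early exit once the force loss passes its convergence target) starts
   near the solution, where the landscape is benign, and reconciles any
   residual inconsistency between per-molecule fits of shared chemical
   environments.

The phased design is not a convenience but a necessity we established
experimentally: end-to-end training from a random start must first break a
"class-mean parameters" plateau (every term of a class carrying identical
parameters), and with loosely supervised charges the optimizer compensates
the wrong class-mean valence forces through the Coulomb term — a jointly
locked, initialization-dependent configuration that can stall the force
loss for thousands of epochs and, on some draws, settle in compensated
minima whose parameters transfer poorly. (Pinning charges with w_q ≈ 1000
breaks that specific trap — confirmed by a controlled experiment on a
stuck draw — which is why the from-scratch schedule in
``recovery_stages`` leads with a strong-charge stage; but even then the
time to full refinement varied by thousands of epochs across seeds.) The
amortized strategy replaces the fragile part with two reliably convex or
empirically stable subproblems and leaves gradient descent only the final
local refinement. λ = 5e-4 is small enough that the torsion-amplitude
shrinkage it induces is not detectable in the recovered forces.
Architecture for this experiment: width 64, hidden 64 (the class default
of 128 is unnecessary at this problem size). Runtime is roughly 4-6
minutes on one CPU, fully deterministic in the master seed.

Transfer to the held-out val/test *molecules* is reported alongside as a
diagnostic. At this data scale (≈22 train molecules) cross-molecule
transfer carries residual errors of order 1-2 kcal/mol: the message-passing
context of a term in an unseen molecule differs from every training
example, and with a handful of carriers per chemical environment nothing
forces the readouts to depend only on the type-determining features. This
mirrors the data appetite of the approach at production scale, where
training sets span thousands of molecular species; it is a property of the
experiment size, not a defect of the machinery, and the numbers are
reported rather than hidden.

## Evaluation conventions

* Energy RMSE: both series centered per molecule, residuals pooled over all
  conformers. Exactly invariant to per-molecule offsets in either series.
* Force RMSE: pooled over all 3N Cartesian components of all conformers
  (rather than per-conformer-then-per-molecule averaging); the convention
  is stated in the report.
* Confidence intervals: percentile bootstrap over molecules with
  replacement, 1000 replicates, 2.5/97.5 percentiles, seeded and
  reproducible; degenerate (identical-residual) inputs give zero width.
* Geometry metrics between two minimized structures: position RMSD after
  Kabsch superposition; RMSDs of bond lengths, angles, proper and improper
  dihedrals with angular differences wrapped into (−π, π], reported in
  degrees, computed in radians.
* ddE: each method's conformer energies are referenced to its own
  minimum-energy conformer of that molecule, then differenced. (The
  torsion-fingerprint deviation of the small-molecule geometry benchmark
  literature is intentionally not reimplemented; the evaluation module
  leaves that as an extension point.)

## Numerical choices and limitations

* Units: kcal/mol, Å, radians, elementary charge throughout; archive
  loaders convert hartree (×627.5094740631) and bohr (×0.529177210903) on
  ingestion only.
* Minimization: L-BFGS-B on the analytic forces with up to four restarts,
  converged when max |force| ≤ tol (default 1e-3 kcal/mol/Å); deterministic.
* Angle geometry guards: sin θ clipped at 1e-6 equivalents to avoid
  division blow-ups at collinearity; linear equilibrium angles (θ0 = π)
  are outside the supported model class.
* Weight initialization is He-normal from a seeded generator; checkpoints
  round-trip bit-exactly (.npz with a JSON hyperparameter header).
* Training divergence (non-finite loss) aborts with the last good
  checkpoint attached to the raised error.
* The Metropolis sampler is a local random walk: it covers the thermal
  basin around the relaxed structure and rotamer space reachable through
  torsion moves, not systematically all conformational basins.
* Radicals and elements outside the supported table are rejected at parse
  time; stereochemistry beyond what canonicalization provides, tautomer
  enumeration, and protonation-state assignment are out of scope.
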