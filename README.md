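# graphff

Machine-learned assignment of Class I molecular-mechanics (MM) force-field
parameters. Instead of discrete atom-typing rules and parameter lookup
tables, `graphff` maps a chemical graph through a message-passing network,
symmetry-preserving (Janossy) pooling over bonds, angles, and proper and
improper torsions, and per-class feed-forward readouts directly to the full
parameter set

    Phi = {K_r, r0, K_theta, theta0, K_phi_n, K_psi_n, q, sigma, epsilon}

of the standard Class I potential

    U(x; Phi) = sum 1/2 K_r (r-r0)^2 + sum 1/2 K_theta (theta-theta0)^2
              + sum sum_n K_phi_n (1 + cos n*phi)
              + sum sum_n K_psi_n (1 + cos n*psi)
              + sum 4 eps [(sigma/r)^12 - (sigma/r)^6] + sum k_e q_i q_j / r.

Partial charges come from a learned charge-equilibration model (predicted
per-atom electronegativity and hardness, closed-form constrained
minimization) that conserves the molecular net charge exactly;
Lennard-Jones sigma/epsilon are transferred from a reference nonbonded
table, never learned. The whole pipeline — including the MM energies and
forces — is differentiable, so the network is trained by matching conformer
energies (centered per molecule), reference forces, and target partial
charges. Parameter assignment happens once per molecular species and is
invariant, to machine precision, under atom reordering, term-index
permutations, and resonance/kekulization changes of the input.

The package is aimed at force-field developers and method researchers who
want a small, fully inspectable, NumPy-based implementation of this
end-to-end differentiable parametrization approach, together with a
self-contained synthetic benchmark: a hand-specified reference force field
with known ground truth, a Metropolis conformer sampler, and an independent
loop-based energy oracle, so the learning pipeline can be validated by
*parameter recovery* without any external data.

## Worked example

```python
from graphff import (ReferenceForceField, build_fixture_set, split_dataset,
                     ForceFieldLearner, LossConfig, ArchConfig, parse_molecule)

ref = ReferenceForceField()
ds = build_fixture_set(seed=0, n_conformers=10,
                       smiles=("CCO", "CCC", "CC=O", "CCN", "c1ccccc1"))
split_dataset(ds, fractions=(0.6, 0.2, 0.2), seed=0)
learner = ForceFieldLearner(ds, ref.lj_table(), arch=ArchConfig(width=32, hidden=32))
fit = learner.fit(LossConfig(seed=0, epochs=400, lr=3e-3, w_charge=100.0,
                             l2_torsion=5e-4))
print(fit.summary())
```

```
Machine-learned MM force field fit
==================================================================
epochs: 400   final loss: 11.5757  (E 0.227 | F 11.2 | q 0.0217 | reg 0.156)
------------------------------------------------------------------
split     mols   confs   E-RMSE (kcal/mol)   F-RMSE (kcal/mol/A)
train        3      30    0.457 [0.137,0.699]     3.370 [2.012,4.199]
val          1      10    4.364 [4.364,4.364]    42.007 [42.007,42.007]
test         1      10    1.448 [1.448,1.448]    13.220 [13.220,13.220]
==================================================================
```

After 400 epochs on three training molecules this abbreviated from-scratch
fit already reproduces the generating force field's conformer energetics on
the training chemistry to ~0.5 kcal/mol (per-molecule-centered RMSE, with
95% molecule-bootstrap confidence intervals); the val/test rows show
transfer to *unseen molecules*, which at this miniature data scale is much
harder — see `docs/methods.md`. The fitted model assigns parameters to any
molecule:

```python
params = fit.parametrize(parse_molecule("CCO"))
for (i, j), k, r0 in zip(params.bond_idx, params.bond_k, params.bond_r0):
    print(f"  bond {i:2d}-{j:2d}   K = {k:6.1f}   r0 = {r0:.3f}")
print(f"partial charges sum to net charge: {params.q.sum():+.12f}")
```

```
  bond  0- 6   K =  413.2   r0 = 0.980
  bond  1- 7   K =  417.9   r0 = 1.043
  bond  2- 7   K =  417.9   r0 = 1.043
  bond  3- 7   K =  417.9   r0 = 1.043
  bond  4- 8   K =  356.7   r0 = 1.081
  bond  5- 8   K =  356.7   r0 = 1.081
  bond  6- 8   K =  324.4   r0 = 1.451
  bond  7- 8   K =  357.7   r0 = 1.491
partial charges sum to net charge: +0.000000000000
```

The generating values for these bonds are 0.979/1.040/1.082/1.453/1.486 A:
the O-H, C-H, C-O and C-C equilibrium lengths are recovered to <= 0.005 A
from energies, forces, and charges alone, and symmetry-equivalent bonds
receive identical parameters by construction. The full recovery experiment
(`graphff.fitting.parameter_recovery`) uses per-molecule linear surface
fits plus network amortization and reaches held-out-conformer errors an
order of magnitude smaller — see `docs/methods.md`.

A command-line surface wraps the same objects:

```bash
graphff make-fixtures --seed 1 --n-conformers 30 --split-seed 1 --out data.h5
graphff train --dataset data.h5 --out run/ --seed 1 --epochs 500
graphff evaluate --checkpoint run/checkpoint.npz --dataset data.h5 --split test
graphff parametrize "CCO" --checkpoint run/checkpoint.npz --out params.json
graphff minimize --params params.json --coords coords.txt --out minimized.txt
```

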