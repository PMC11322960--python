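"""Model/Results interface tying the pipeline together.

:class:`ForceFieldLearner` is the model object: it owns a conformer dataset,
the reference Lennard-Jones table, and the architecture, and ``fit()``
returns a :class:`ForceFieldFit` results object carrying the trained
weights, the loss history, per-split metrics with bootstrap uncertainties,
and a ``summary()`` table. Parameter assignment for new molecules and
conformer-energy prediction hang off the results object.

:func:`parameter_recovery` is the package's canonical end-to-end
experiment: generate the synthetic dataset, split it by molecule, train,
and measure how well the learned model reproduces the generating force
field's energies and forces on conformers never seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import model as model_mod
from .chemgraph import Molecule
from .data import MoleculeDataset
from .evaluation import MetricReport, evaluate_dataset
from .fixtures import ReferenceForceField, build_fixture_set, sample_conformers
from .mmpotential import GeometryCache, energy_total, forces_batch
from .nnet import AdamOptimizer
from .training import (ArchConfig, LossConfig, center_energies, split_dataset,
                       train)

__all__ = ["ForceFieldLearner", "ForceFieldFit", "parameter_recovery",
           "recovery_stages"]


def recovery_stages(seed: int):
    """Optimization schedule used by the recovery experiment.

    Stage 1 briefly pins the charges with very strong supervision
    (w_q = 1000): with loose charges, the optimizer compensates the early
    class-mean valence forces through the Coulomb term, and that joint
    configuration can trap training on a long plateau; with charges held at
    their (exact) targets, the valence problem is linear in the readout
    outputs and descends freely. The pinning stage is kept short — just
    long enough to break the trap — because prolonged charge domination of
    the shared trunk measurably slows the later valence refinement. Stage 2
    is the balanced workhorse; stages 3-4 anneal the rate to refine
    equilibrium values and torsion amplitudes. The torsion L2 is light so
    it does not bias amplitudes detectably.
    """
    return (
        LossConfig(seed=seed, epochs=400, lr=3e-3, w_charge=1000.0,
                   l2_torsion=5e-4),
        LossConfig(seed=seed, epochs=1200, lr=3e-3, w_charge=100.0,
                   l2_torsion=5e-4),
        # long, gently annealed refinement: the force valley needs
        # progressively smaller steps (a constant rate bounces at a high
        # noise floor) and late-differentiating runs need the full horizon;
        # runs that reach the convergence target early exit to the polish
        LossConfig(seed=seed, epochs=4400, lr=1e-3, lr_decay=0.9995,
                   w_charge=100.0, l2_torsion=5e-4, stop_below_force=0.5),
        LossConfig(seed=seed, epochs=800, lr=1e-4, lr_decay=0.998,
                   w_charge=100.0, l2_torsion=5e-4),
    )


@dataclass
class ForceFieldLearner:
    """Learnable MM parametrization model bound to a dataset."""

    dataset: MoleculeDataset
    lj_table: model_mod.LennardJonesTable
    arch: ArchConfig = field(default_factory=ArchConfig)

    def fit(self, stages, callback=None, n_restarts: int = 1,
            race_epochs: int = 300,
            initial_weights: model_mod.ModelWeights | None = None
            ) -> "ForceFieldFit":
        """Train through one or more :class:`LossConfig` stages.

        With ``n_restarts > 1`` the first ``race_epochs`` of stage 1 are run
        from that many different (seed-derived) initializations and the run
        with the lowest force loss is continued. Whether the optimizer
        breaks out of the early "class-mean parameters" plateau — where
        every term of a class carries the same parameters — within a given
        epoch budget depends strongly on the initialization draw; racing a
        few candidates makes the schedule robust to that lottery while
        staying fully deterministic in the master seed.
        """
        if isinstance(stages, LossConfig):
            stages = (stages,)
        first = stages[0]
        histories = []
        optimizer = None
        if initial_weights is not None:
            weights = initial_weights
            optimizer = AdamOptimizer(weights.params, lr=first.lr,
                                      lr_decay=first.lr_decay,
                                      weight_decay=first.weight_decay)
            remaining = stages
        elif n_restarts > 1 and first.epochs > race_epochs:
            best = None
            for k in range(n_restarts):
                cfg_k = replace(first, epochs=race_epochs,
                                seed=(first.seed + 101 * k) % (2 ** 31 - 1))
                w_k = model_mod.init_weights(
                    width=self.arch.width, hidden=self.arch.hidden,
                    n_layers=self.arch.n_layers, seed=cfg_k.seed)
                opt_k = AdamOptimizer(w_k.params, lr=cfg_k.lr,
                                      lr_decay=cfg_k.lr_decay,
                                      weight_decay=cfg_k.weight_decay)
                w_k, h_k = train(self.dataset, cfg_k, self.lj_table,
                                 arch=self.arch, callback=callback,
                                 weights=w_k, optimizer=opt_k)
                score = float(h_k["force"].iloc[-1])
                if best is None or score < best[0]:
                    best = (score, w_k, h_k, opt_k, cfg_k.seed)
            _, weights, hist, optimizer, win_seed = best
            histories.append(hist)
            # the winner keeps its optimizer state: restarting Adam discards
            # the second moments and can undo the escape just achieved
            rest = replace(first, epochs=first.epochs - race_epochs,
                           seed=win_seed)
            weights, hist = train(self.dataset, rest, self.lj_table,
                                  arch=self.arch, callback=callback,
                                  weights=weights, optimizer=optimizer)
            histories.append(hist)
            remaining = stages[1:]
        else:
            weights = None
            remaining = stages
        if weights is None and remaining:
            cfg0 = remaining[0]
            weights = model_mod.init_weights(
                width=self.arch.width, hidden=self.arch.hidden,
                n_layers=self.arch.n_layers, seed=cfg0.seed)
            optimizer = AdamOptimizer(weights.params, lr=cfg0.lr,
                                      lr_decay=cfg0.lr_decay,
                                      weight_decay=cfg0.weight_decay)
        for cfg in remaining:
            weights, hist = train(self.dataset, cfg, self.lj_table,
                                  arch=self.arch, callback=callback,
                                  weights=weights, optimizer=optimizer)
            histories.append(hist)
        history = pd.concat(histories, ignore_index=True)
        history["epoch"] = np.arange(len(history))
        return ForceFieldFit(model=self, weights=weights, history=history,
                             stages=tuple(stages))


@dataclass
class ForceFieldFit:
    """Results of a fit: weights, history, metrics, and prediction."""

    model: ForceFieldLearner
    weights: model_mod.ModelWeights
    history: pd.DataFrame
    stages: tuple

    def parametrize(self, mol: Molecule) -> model_mod.MMParameterSet:
        return model_mod.parametrize(mol, self.weights, self.model.lj_table)

    def predict(self, mol: Molecule, coords: np.ndarray):
        """Energies (C,) and forces (C,N,3) for conformers of ``mol``."""
        params = self.parametrize(mol)
        cache = GeometryCache(params, coords)
        return energy_total(params, cache), forces_batch(params, cache)

    def evaluate(self, split: str = "test", n_boot: int = 1000,
                 seed: int = 0) -> MetricReport:
        entries = [e for e in self.model.dataset.entries if e.split == split]
        return evaluate_dataset(self.weights, entries, self.model.lj_table,
                                n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        """Formatted per-split metric table with 95% bootstrap CIs."""
        last = self.history.iloc[-1]
        lines = [
            "Machine-learned MM force field fit",
            "=" * 66,
            f"epochs: {len(self.history)}   "
            f"final loss: {last['total']:.6g}  "
            f"(E {last['energy']:.3g} | F {last['force']:.3g} | "
            f"q {last['charge']:.3g} | reg {last['reg']:.3g})",
            "-" * 66,
            f"{'split':8s}{'mols':>6s}{'confs':>8s}"
            f"{'E-RMSE (kcal/mol)':>20s}{'F-RMSE (kcal/mol/A)':>22s}",
        ]
        for split in ("train", "val", "test"):
            entries = [e for e in self.model.dataset.entries
                       if e.split == split]
            if not entries:
                continue
            rep = self.evaluate(split, n_boot=200)
            lines.append(
                f"{split:8s}{rep.n_molecules:>6d}{rep.n_conformers:>8d}"
                f"{rep.energy_rmse:>9.3f} [{rep.energy_ci[0]:.3f},"
                f"{rep.energy_ci[1]:.3f}]"
                f"{rep.force_rmse:>10.3f} [{rep.force_ci[0]:.3f},"
                f"{rep.force_ci[1]:.3f}]")
        lines.append("=" * 66)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# amortized fitting: per-molecule linear surface fits -> network regression
# -> end-to-end fine-tune.
#
# With charges fixed at their targets and Lennard-Jones transferred, the
# centered conformer energies and all force components are LINEAR in the
# valence unknowns when bonds/angles are expressed in natural coordinates
# (K, K*x0) — the leftover P^2/2K constants are conformer-independent and
# vanish under centering — and in the torsion amplitudes. Each molecule's
# valence parameters are therefore recovered by a ridge-regularized linear
# least squares on its own conformers: deterministic, instant, and immune
# to the plateaus and basin lotteries of end-to-end gradient descent from a
# random start. The network is then trained to reproduce those per-molecule
# fits (plain supervised regression in raw-output space), and finally
# fine-tuned end to end with the standard energy/force/charge loss, which
# starts near the solution where the landscape is benign.


def _valence_design_matrix(pc, q, w_energy=1.0, w_force=1.0):
    """Stacked linear system (A, b) for one molecule's valence parameters.

    Unknown vector layout: [bond K | bond K*r0 | angle K | angle K*theta0 |
    proper amps (6 per torsion) | improper amps (2 per improper)].
    Rows: per-conformer centered energies, then all force components.
    """
    cache = pc.cache
    C, N = cache.n_conf, cache.n_atoms
    B, A_, P, I = (len(cache.bond_idx), len(cache.angle_idx),
                   len(cache.proper_idx),
                   len(cache.improper_arr_idx) // 3)
    ncol = 2 * B + 2 * A_ + 6 * P + 2 * I
    nF = C * N * 3
    A_E = np.zeros((C, ncol))
    A_F = np.zeros((C, N, 3, ncol))
    col = 0
    # bonds: E += 1/2 K r^2 - P r ; F_i = (-K r + P) u, F_j = -F_i
    for b in range(B):
        i, j = cache.bond_idx[b]
        r = cache.bond_r[:, b]
        u = cache.bond_u[:, b, :]
        A_E[:, col + b] = 0.5 * r * r
        A_F[:, i, :, col + b] += -r[:, None] * u
        A_F[:, j, :, col + b] += r[:, None] * u
        A_E[:, col + B + b] = -r
        A_F[:, i, :, col + B + b] += u
        A_F[:, j, :, col + B + b] += -u
    col += 2 * B
    for a in range(A_):
        th = cache.theta[:, a]
        A_E[:, col + a] = 0.5 * th * th
        A_E[:, col + A_ + a] = -th
        for pos, g in ((0, cache.ang_gi), (1, cache.ang_gj), (2, cache.ang_gk)):
            atom = cache.angle_idx[a, pos]
            A_F[:, atom, :, col + a] += -th[:, None] * g[:, a, :]
            A_F[:, atom, :, col + A_ + a] += g[:, a, :]
    col += 2 * A_
    ns = np.arange(1, 7, dtype=float)
    for p in range(P):
        phi = cache.proper_phi[:, p]
        for k, n in enumerate(ns):
            A_E[:, col + 6 * p + k] = 1.0 + np.cos(n * phi)
            for pos in range(4):
                atom = cache.proper_idx[p, pos]
                A_F[:, atom, :, col + 6 * p + k] += (
                    n * np.sin(n * phi)[:, None] * cache.proper_g[:, p, pos, :])
    col += 6 * P
    ns2 = np.arange(1, 3, dtype=float)
    for m in range(I):
        for arr in range(3):
            t = 3 * m + arr
            psi = cache.improper_psi[:, t]
            for k, n in enumerate(ns2):
                A_E[:, col + 2 * m + k] += 1.0 + np.cos(n * psi)
                for pos in range(4):
                    atom = cache.improper_arr_idx[t, pos]
                    A_F[:, atom, :, col + 2 * m + k] += (
                        n * np.sin(n * psi)[:, None]
                        * cache.improper_g[:, t, pos, :])

    # nonbonded contribution with the fixed charges moves to the rhs
    nb_params = model_mod.MMParameterSet(
        n_atoms=N, net_charge=pc.entry.molecule.net_charge,
        bond_idx=cache.bond_idx, bond_k=np.zeros(B), bond_r0=np.ones(B),
        angle_idx=cache.angle_idx, angle_k=np.zeros(A_),
        angle_theta0=np.full(A_, 1.9),
        proper_idx=cache.proper_idx, proper_k=np.zeros((P, 6)),
        improper_idx=cache.improper_arr_idx[::3][:, [1, 0, 2, 3]] if I else
        np.zeros((0, 4), dtype=np.int64),
        improper_k=np.zeros((I, 2)),
        q=q, sigma=pc.sigma, epsilon=pc.epsilon)
    e_nb = energy_total(nb_params, cache)
    f_nb = forces_batch(nb_params, cache)
    b_E = center_energies(np.asarray(pc.entry.qm_energies)) - center_energies(e_nb)
    b_F = (-pc.entry.qm_gradients) - f_nb

    # center the energy design rows over conformers (predictions are centered)
    A_E = A_E - A_E.mean(axis=0, keepdims=True)
    A_stack = np.vstack([np.sqrt(w_energy) * A_E,
                         np.sqrt(w_force) * A_F.reshape(nF, ncol)])
    b_stack = np.concatenate([np.sqrt(w_energy) * b_E,
                              np.sqrt(w_force) * b_F.reshape(nF)])
    sizes = (B, A_, P, I)
    return A_stack, b_stack, sizes


def fit_molecule_valence(pc, q, ridge=1.0):
    """Ridge least-squares valence parameters for one molecule.

    Solved around physical priors in scaled coordinates, so directions the
    molecule's conformers do not determine stay at the priors instead of
    drifting unphysically. Returns a dict of per-class arrays.
    """
    A, b, (B, A_, P, I) = _valence_design_matrix(pc, q)
    prior = np.concatenate([
        np.full(B, 400.0), np.full(B, 520.0),
        np.full(A_, 80.0), np.full(A_, 160.0),
        np.zeros(6 * P), np.zeros(2 * I)])
    scale = np.concatenate([
        np.full(B, 150.0), np.full(B, 150.0),
        np.full(A_, 40.0), np.full(A_, 60.0),
        np.full(6 * P, 1.0), np.full(2 * I, 1.0)])
    # solve for x with theta = prior + scale * x, ridge on x
    As = A * scale
    rhs = b - A @ prior
    n = As.shape[1]
    reg = np.sqrt(ridge) * np.eye(n)
    x, *_ = np.linalg.lstsq(np.vstack([As, reg]),
                            np.concatenate([rhs, np.zeros(n)]), rcond=None)
    theta = prior + scale * x
    out = {
        "bond_k": theta[:B], "bond_p": theta[B:2 * B],
        "angle_k": theta[2 * B:2 * B + A_],
        "angle_p": theta[2 * B + A_:2 * B + 2 * A_],
        "proper_k": theta[2 * B + 2 * A_:2 * B + 2 * A_ + 6 * P].reshape(P, 6),
        "improper_k": theta[2 * B + 2 * A_ + 6 * P:].reshape(I, 2),
    }
    # keep force constants positive (weakly determined terms only)
    out["bond_k"] = np.maximum(out["bond_k"], 20.0)
    out["bond_p"] = np.maximum(out["bond_p"], 0.8 * out["bond_k"])
    out["angle_k"] = np.maximum(out["angle_k"], 10.0)
    out["angle_p"] = np.maximum(out["angle_p"], 1.0 * out["angle_k"])
    return out


def _raw_targets_from_valence(val):
    """Invert the output maps: per-term raw readout values for regression."""
    from .nnet import softplus_inv
    from .model import (KR_SCALE, KR0_SCALE, KTH_SCALE, KTH0_SCALE, K_FLOOR,
                        P_FLOOR)

    def spi(x, lo=1e-6):
        return softplus_inv(np.maximum(x, lo))

    raw = {}
    raw["bond"] = np.stack([
        spi((val["bond_k"] - K_FLOOR) / KR_SCALE),
        spi((val["bond_p"] - P_FLOOR) / KR0_SCALE)], axis=1)
    theta0 = np.clip(val["angle_p"] / val["angle_k"], 0.6, np.pi - 0.15)
    # invert the near-identity sigmoid squash on theta0
    ratio = np.pi / 2 + (np.pi / 4) * np.log(theta0 / (np.pi - theta0))
    raw["angle"] = np.stack([
        spi((val["angle_k"] - K_FLOOR) / KTH_SCALE),
        spi((ratio * val["angle_k"] - P_FLOOR) / KTH0_SCALE)], axis=1)
    raw["proper"] = val["proper_k"].copy()
    raw["improper"] = val["improper_k"].copy()
    return raw


def _charge_raw_targets(q_target):
    """Raw charge-head targets reproducing ``q_target`` through equilibration
    with uniform hardness s0 (then e_i = -2 s0 q_i up to a constant)."""
    from .nnet import softplus_inv
    from .model import E_SCALE, S_FLOOR, S_SCALE
    s0 = 100.0
    e = -2.0 * s0 * np.asarray(q_target, dtype=np.float64)
    raw = np.zeros((len(e), 2))
    raw[:, 0] = e / E_SCALE
    raw[:, 1] = float(softplus_inv((s0 - S_FLOOR) / S_SCALE))
    return raw


def amortize_network(pre, targets, charge_targets, arch, seed,
                     epochs=2500, lr=3e-3, lr_decay=0.999, callback=None):
    """Supervised regression of the network onto per-molecule raw targets."""
    weights = model_mod.init_weights(width=arch.width, hidden=arch.hidden,
                                     n_layers=arch.n_layers, seed=seed)
    opt = AdamOptimizer(weights.params, lr=lr, lr_decay=lr_decay)
    n_terms = {cls: max(1, sum(len(t[cls]) for t in targets))
               for cls in ("bond", "angle", "proper", "improper")}
    n_atoms = max(1, sum(len(c) for c in charge_targets))
    for epoch in range(epochs):
        grads = {k: np.zeros_like(v) for k, v in weights.params.items()}
        total = 0.0
        for pc, tgt, ctgt in zip(pre, targets, charge_targets):
            fwd = model_mod.network_forward(pc.graph, pc.topo, weights)
            draw = {}
            for cls in ("bond", "angle", "proper", "improper"):
                diff = fwd.raw[cls] - tgt[cls]
                total += float(np.sum(diff ** 2)) / n_terms[cls]
                draw[cls] = 2.0 * diff / n_terms[cls]
            dcr = 2.0 * (fwd.charge_raw - ctgt) / n_atoms
            total += float(np.sum((fwd.charge_raw - ctgt) ** 2)) / n_atoms
            for k, v in model_mod.network_backward(weights, fwd, draw,
                                                   dcr).items():
                grads[k] += v
        opt.step(weights.params, grads)
        if callback is not None and epoch % 250 == 0:
            callback(epoch, weights, {"regression": total})
    return weights


def parameter_recovery(seed: int, n_conformers: int = 30,
                       n_heldout_conformers: int = 10,
                       arch: ArchConfig | None = None,
                       stages=None, callback=None) -> dict:
    """End-to-end recovery experiment against the synthetic ground truth.

    Builds the fixture dataset with ``seed``, splits molecules 80:10:10,
    trains the model on the train split, then measures centered-energy and
    force RMSE on freshly sampled conformers of the fitted molecules —
    geometries never seen during training — against the reference force
    field. Cross-molecule transfer to the held-out val/test molecules is
    reported alongside as a diagnostic.
    """
    from .training import _precompute

    seed = int(seed) % (2 ** 31 - 1)
    ref = ReferenceForceField()
    ds = build_fixture_set(seed=seed, n_conformers=n_conformers)
    split_dataset(ds, seed=seed)
    lj = ref.lj_table()
    arch = arch or ArchConfig(width=64, hidden=64)
    learner = ForceFieldLearner(ds, lj, arch=arch)
    if stages is not None:
        fit = learner.fit(stages, callback=callback, n_restarts=3)
    else:
        # amortized strategy: per-molecule linear surface fits, supervised
        # network regression onto them, then end-to-end fine-tuning
        train_entries = [e for e in ds.entries if e.split == "train"]
        pre = _precompute(train_entries, lj)
        targets = [_raw_targets_from_valence(
            fit_molecule_valence(pc, pc.q_target)) for pc in pre]
        charge_targets = [_charge_raw_targets(pc.q_target) for pc in pre]
        w0 = amortize_network(pre, targets, charge_targets, arch, seed,
                              callback=callback)
        finetune = (
            LossConfig(seed=seed, epochs=1500, lr=3e-4, lr_decay=0.9985,
                       w_charge=100.0, l2_torsion=5e-4,
                       stop_below_force=0.05),
        )
        fit = learner.fit(finetune, callback=callback, initial_weights=w0)

    train_mols = [e.molecule for e in ds.entries if e.split == "train"]
    se_e = n_e = se_f = n_f = 0.0
    for i, mol in enumerate(train_mols):
        rng = np.random.default_rng([seed, 900_000 + i])
        coords, energies, grads = sample_conformers(
            ref, mol, n_heldout_conformers, rng)
        e_mm, f_mm = fit.predict(mol, coords)
        resid = center_energies(e_mm) - center_energies(energies)
        se_e += float(resid @ resid)
        n_e += resid.size
        fresid = f_mm + grads
        se_f += float(np.sum(fresid ** 2))
        n_f += fresid.size
    out = {
        "fit": fit,
        "heldout_energy_rmse": float(np.sqrt(se_e / n_e)),
        "heldout_force_rmse": float(np.sqrt(se_f / n_f)),
    }
    for split in ("val", "test"):
        try:
            rep = fit.evaluate(split, n_boot=200, seed=seed)
        except ValueError:
            continue
        out[f"{split}_energy_rmse"] = rep.energy_rmse
        out[f"{split}_force_rmse"] = rep.force_rmse
    return out
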