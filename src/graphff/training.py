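"""Fitting the parametrization network to conformer energies, forces, and
target charges.

The loss is

    L = w_E * MSE(centered MM energies, centered reference energies)
      + w_F * MSE(MM forces, -reference gradients)
      + w_q * MSE(predicted charges, target charges)
      + l2  * (sum K_proper^2 + sum K_improper^2)

with energies centered per molecule (the same operator applied to both
series, removing the per-molecule offset that an MM functional form cannot
represent), force error pooled over all 3N Cartesian components, and L2
regularization on proper/improper torsion amplitudes only. Optimization is
full-batch Adam; geometry factors for every conformer are precomputed once,
so an epoch is a network forward/backward plus tensor contractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import charges as charges_mod
from . import model as model_mod
from .data import MoleculeDataset
from .mmpotential import (GeometryCache, energy_total, forces_batch,
                          parameter_gradients)
from .nnet import AdamOptimizer

__all__ = ["LossConfig", "ArchConfig", "center_energies", "split_dataset",
           "loss", "train", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    def __init__(self, message, weights, history):
        super().__init__(message)
        self.weights = weights
        self.history = history


@dataclass
class ArchConfig:
    width: int = 128
    hidden: int = 128
    n_layers: int = 3


@dataclass
class LossConfig:
    """Loss weights, regularization, and optimizer settings.

    The seed is mandatory: it fixes weight initialization and hence the
    entire training trajectory (full-batch updates have no other source of
    randomness).
    """

    seed: int
    w_energy: float = 1.0
    w_force: float = 1.0
    w_charge: float = 1.0
    l2_torsion: float = 0.01
    lr: float = 1e-3
    lr_decay: float = 1.0
    weight_decay: float = 0.0
    epochs: int = 500
    #: optional convergence target: stop once the (weighted) force loss
    #: component falls below this value; None trains for all epochs
    stop_below_force: float | None = None

    def __post_init__(self):
        if min(self.w_energy, self.w_force, self.w_charge, self.l2_torsion) < 0:
            raise ValueError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# centering and splitting


def center_energies(energies: np.ndarray) -> np.ndarray:
    """Subtract the mean; idempotent; a single conformer maps to 0."""
    energies = np.asarray(energies, dtype=np.float64)
    return energies - energies.mean()


def split_dataset(ds: MoleculeDataset, fractions=(0.8, 0.1, 0.1),
                  seed: int = 0, overrides: dict | None = None) -> MoleculeDataset:
    """Assign train/val/test labels by molecule (canonical identity).

    Shuffles unique identities with the seed and cuts at the given
    fractions (any rounding remainder goes to train). Entries sharing an
    identity are co-assigned. ``overrides`` maps identity -> split label and
    is applied last (asymmetric train-only/test-only designs).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = ("train", "val", "test")
    idents = sorted(set(ds.identities()))
    if len(idents) < len(fractions):
        raise ValueError("fewer molecules than splits")
    order = np.random.default_rng(seed).permutation(len(idents))
    shuffled = [idents[i] for i in order]
    n = len(shuffled)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    assignment = {}
    for pos, ident in enumerate(shuffled):
        if pos < n_train:
            assignment[ident] = labels[0]
        elif pos < n_train + n_val:
            assignment[ident] = labels[1]
        else:
            assignment[ident] = labels[2]
    if overrides:
        assignment.update(overrides)
    for e in ds.entries:
        e.split = assignment[e.molecule.identity]
    return ds


# ---------------------------------------------------------------------------
# precomputation


def _precompute(entries, lj_table):
    """Geometry caches, topologies, and reference arrays, built once."""
    from .chemgraph import enumerate_terms, featurize

    pre = []
    for e in entries:
        graph = featurize(e.molecule)
        topo = enumerate_terms(graph)
        skel = SimpleNamespace(n_atoms=e.molecule.n_atoms,
                               bond_idx=topo.bonds, angle_idx=topo.angles,
                               proper_idx=topo.propers,
                               improper_idx=topo.impropers)
        cache = GeometryCache(skel, e.coords)
        sigma, epsilon = lj_table.lookup(e.molecule)
        pre.append(SimpleNamespace(
            entry=e, graph=graph, topo=topo, cache=cache,
            sigma=sigma, epsilon=epsilon,
            e_ref_centered=center_energies(e.qm_energies),
            f_ref=-e.qm_gradients,
            q_target=np.asarray(e.target_charges, dtype=np.float64)))
    return pre


def _assemble_params(fwd, pc, mol):
    e, s = charges_mod.charge_head_maps(fwd.charge_raw)
    q = charges_mod.equilibrate(e, s, mol.net_charge)
    val = fwd.valence
    params = model_mod.MMParameterSet(
        n_atoms=mol.n_atoms, net_charge=mol.net_charge,
        bond_idx=pc.topo.bonds, bond_k=val["bond_k"], bond_r0=val["bond_r0"],
        angle_idx=pc.topo.angles, angle_k=val["angle_k"],
        angle_theta0=val["angle_theta0"],
        proper_idx=pc.topo.propers, proper_k=val["proper_k"],
        improper_idx=pc.topo.impropers, improper_k=val["improper_k"],
        q=q, sigma=pc.sigma, epsilon=pc.epsilon)
    return params, e, s


# ---------------------------------------------------------------------------
# loss


def loss(w: model_mod.ModelWeights, batch, cfg: LossConfig, lj_table,
         precomp=None, with_grads: bool = True):
    """Loss and (optionally) gradients for a batch of molecule entries.

    Returns ``(total, components, grads)`` where components holds the
    energy/force/charge/regularization terms and grads is a flat dict over
    all learnable tensors (None when ``with_grads`` is False).
    """
    pre = precomp if precomp is not None else _precompute(batch, lj_table)
    n_conf_total = sum(p.cache.n_conf for p in pre)
    n_force_comp = sum(p.cache.n_conf * p.cache.n_atoms * 3 for p in pre)
    n_atoms_total = sum(p.entry.molecule.n_atoms for p in pre)

    comp = {"energy": 0.0, "force": 0.0, "charge": 0.0, "reg": 0.0}
    grads = {k: np.zeros_like(v) for k, v in w.params.items()} if with_grads else None

    for pc in pre:
        mol = pc.entry.molecule
        fwd = model_mod.network_forward(pc.graph, pc.topo, w)
        params, e_head, s_head = _assemble_params(fwd, pc, mol)

        e_mm = energy_total(params, pc.cache)
        e_mm_c = center_energies(e_mm)
        resid_e = e_mm_c - pc.e_ref_centered
        comp["energy"] += cfg.w_energy * float(resid_e @ resid_e) / n_conf_total

        dF = None
        if cfg.w_force > 0:
            f_mm = forces_batch(params, pc.cache)
            resid_f = f_mm - pc.f_ref
            comp["force"] += cfg.w_force * float(np.sum(resid_f ** 2)) / n_force_comp
        resid_q = params.q - pc.q_target
        comp["charge"] += cfg.w_charge * float(resid_q @ resid_q) / n_atoms_total
        comp["reg"] += cfg.l2_torsion * (float(np.sum(params.proper_k ** 2))
                                         + float(np.sum(params.improper_k ** 2)))
        if not with_grads:
            continue

        # adjoints: dL/dE per conformer (centering is symmetric/idempotent,
        # and the reference is already centered, so centering the residual
        # is the exact chain rule), dL/dF per component, dL/dq per atom
        dE = 2.0 * cfg.w_energy * center_energies(resid_e) / n_conf_total
        if cfg.w_force > 0:
            dF = 2.0 * cfg.w_force * resid_f / n_force_comp
        pg = parameter_gradients(params, pc.cache, dE, dF)
        pg["proper_k"] = pg["proper_k"] + 2.0 * cfg.l2_torsion * params.proper_k
        pg["improper_k"] = pg["improper_k"] + 2.0 * cfg.l2_torsion * params.improper_k
        dq = pg.pop("q") + 2.0 * cfg.w_charge * resid_q / n_atoms_total

        draw = model_mod.valence_map_backward(
            fwd.raw, {"bond_k": pg["bond_k"], "bond_r0": pg["bond_r0"],
                      "angle_k": pg["angle_k"],
                      "angle_theta0": pg["angle_theta0"],
                      "proper_k": pg["proper_k"],
                      "improper_k": pg["improper_k"]})
        de, ds = charges_mod.equilibrate_backward(e_head, s_head,
                                                  mol.net_charge, dq)
        dcharge_raw = charges_mod.charge_head_map_backward(fwd.charge_raw, de, ds)
        for key, val in model_mod.network_backward(w, fwd, draw, dcharge_raw).items():
            grads[key] += val

    total = sum(comp.values())
    return total, comp, grads


# ---------------------------------------------------------------------------
# training loop


def train(ds: MoleculeDataset, cfg: LossConfig, lj_table,
          arch: ArchConfig = ArchConfig(), callback=None,
          weights: model_mod.ModelWeights | None = None,
          optimizer: AdamOptimizer | None = None):
    """Fit model weights on the train split of ``ds``.

    Fully reproducible given ``cfg.seed``. Returns ``(weights, history)``
    with a per-epoch record of every loss component. Divergence (non-finite
    loss) raises :class:`TrainingDiverged` carrying the last good weights.
    """
    entries = [e for e in ds.entries if e.split == "train"]
    if not entries:
        raise ValueError("no molecules labeled 'train' in the dataset")
    pre = _precompute(entries, lj_table)
    if weights is None:
        weights = model_mod.init_weights(width=arch.width, hidden=arch.hidden,
                                         n_layers=arch.n_layers, seed=cfg.seed)
    if optimizer is None:
        opt = AdamOptimizer(weights.params, lr=cfg.lr, lr_decay=cfg.lr_decay,
                            weight_decay=cfg.weight_decay)
    else:
        opt = optimizer
        opt.reconfigure(lr=cfg.lr, lr_decay=cfg.lr_decay,
                        weight_decay=cfg.weight_decay)
    history = []
    last_good = weights.copy()
    for epoch in range(cfg.epochs):
        total, comp, grads = loss(weights, entries, cfg, lj_table, precomp=pre)
        if not np.isfinite(total):
            hist = pd.DataFrame(history)
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch}", last_good, hist)
        if epoch % 10 == 0:
            last_good = weights.copy()
        opt.step(weights.params, grads)
        rec = {"epoch": epoch, "total": total, **comp}
        history.append(rec)
        if callback is not None:
            callback(epoch, weights, rec)
        if (cfg.stop_below_force is not None
                and comp["force"] < cfg.stop_below_force):
            break
    return weights, pd.DataFrame(history)
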