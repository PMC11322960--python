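"""Three-stage parametrization network: atom embeddings, symmetry-preserving
term pooling, and feed-forward readout to molecular-mechanics parameters.

Stage 1 is a message-passing graph network (sum aggregation over bonded
neighbors, ReLU, 3 layers by default) producing one latent vector per atom.
Stage 2 builds per-term feature vectors that are exactly invariant under the
physical index symmetries of each term class by summing a feed-forward
network over the equivalent orderings (Janossy pooling):

* bond (i,j):            f(h_i|h_j) + f(h_j|h_i)
* angle (i,j,k):         g(h_i|h_j|h_k) + g(h_k|h_j|h_i)
* proper (i,j,k,l):      t(h_i|h_j|h_k|h_l) + t(h_l|h_k|h_j|h_i)
* improper (c;a,b,d):    sum over the 3 cyclic arrangements of the outer
                         atoms of u(h_c|h_x|h_y|h_z), central atom fixed

Stage 3 maps term vectors to parameters through smooth range maps: each
harmonic class emits (K, K*x0) through scaled softplus outputs — strictly
positive, and linear in the energy/force model, which keeps the fitting
landscape benign (see the scale-constant comments below) — from which the
equilibrium value x0 is recovered as the ratio; torsion amplitudes are
linear (sign-free, phase fixed at 0). Lennard-Jones
sigma/epsilon are never learned: they are copied from a reference nonbonded
table keyed by the reference force field's own atom typing. Partial charges
come from the charge-equilibration head (see :mod:`graphff.charges`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .chemgraph import (ChemicalGraph, Molecule, TermTopology, N_FEATURES,
                        enumerate_terms, featurize)

__all__ = [
    "ConfigurationError", "ParametrizationError",
    "ModelWeights", "init_weights",
    "LennardJonesTable", "MMParameterSet",
    "embed_atoms", "pool_terms", "readout_parameters", "parametrize",
    "network_forward", "network_backward", "apply_valence_maps",
    "valence_map_backward",
]


class ConfigurationError(ValueError):
    pass


class ParametrizationError(ValueError):
    pass


# output-map scale constants (kcal/mol, Å, rad units; see docs/methods.md)
#
# Harmonic terms are emitted in "natural" coordinates (K, K*x0): the energy
# 1/2 K (x - x0)^2 = 1/2 K x^2 - (K x0) x + const is linear in both outputs
# (the constant is removed by per-molecule energy centering), which keeps the
# loss surface free of the self-locking saddle of the (K, x0) coordinates,
# where a wrong x0 makes K -> 0 optimal and K -> 0 in turn kills the x0
# gradient. x0 = (K x0)/K is recovered after the map; positivity of both
# softplus outputs guarantees K > 0 and x0 > 0.
KR_SCALE = 400.0       # bond force constant scale
KR0_SCALE = 520.0      # bond K*r0 product scale
KTH_SCALE = 100.0      # angle force constant scale
KTH0_SCALE = 160.0     # angle K*theta0 product scale
K_FLOOR = 1e-3         # positivity floor on harmonic force constants
P_FLOOR = 1.0          # floor on the K*x0 products: keeps x0 strictly
                       # positive even if a product channel saturates low
TOR_SCALE = 1.0        # linear scale on torsion amplitudes
E_SCALE = 50.0         # electronegativity scale (kcal/mol/e)
S_SCALE = 50.0         # hardness scale (kcal/mol/e^2)
S_FLOOR = 1.0          # hardness floor, keeps equilibration well-posed

N_PROPER_PERIODICITIES = 6   # n = 1..6, phases fixed at 0
N_IMPROPER_PERIODICITIES = 2  # n = 1,2, phases fixed at 0

_TERM_CLASSES = ("bond", "angle", "proper", "improper")
_ARITY = {"bond": 2, "angle": 3, "proper": 4, "improper": 4}
_PERMS = {
    "bond": [(0, 1), (1, 0)],
    "angle": [(0, 1, 2), (2, 1, 0)],
    "proper": [(0, 1, 2, 3), (3, 2, 1, 0)],
    # rows are (central, a, b, d); the 3 cyclic arrangements of the outer atoms
    "improper": [(0, 1, 2, 3), (0, 2, 3, 1), (0, 3, 1, 2)],
}
_N_OUT = {"bond": 2, "angle": 2, "proper": N_PROPER_PERIODICITIES,
          "improper": N_IMPROPER_PERIODICITIES}


# ---------------------------------------------------------------------------
# weights


@dataclass
class ModelWeights:
    """All learnable tensors plus the hyperparameters that shape them."""

    params: dict
    hyper: dict

    def copy(self) -> "ModelWeights":
        return ModelWeights({k: v.copy() for k, v in self.params.items()},
                            dict(self.hyper))

    def save(self, path: str):
        header = json.dumps(self.hyper, sort_keys=True)
        with open(path, "wb") as fh:
            np.savez(fh, __hyper__=np.frombuffer(header.encode(), dtype=np.uint8),
                     **self.params)

    @classmethod
    def load(cls, path: str) -> "ModelWeights":
        with np.load(path) as data:
            hyper = json.loads(bytes(data["__hyper__"]).decode())
            params = {k: data[k].copy() for k in data.files if k != "__hyper__"}
        return cls(params=params, hyper=hyper)


def _readout_bias(cls: str):
    """Final-layer biases so a freshly initialized net emits physical priors."""
    if cls == "bond":
        # priors: K ~ 400 kcal/mol/Å^2, r0 ~ 1.3 Å (K*r0 ~ 520)
        return [float(nnet.softplus_inv(1.0)), float(nnet.softplus_inv(1.0))]
    if cls == "angle":
        # priors: K ~ 80 kcal/mol/rad^2, theta0 ~ 2.0 rad (K*theta0 ~ 160)
        return [float(nnet.softplus_inv(0.8)), float(nnet.softplus_inv(1.0))]
    return [0.0] * _N_OUT[cls]


def init_weights(width: int = 128, hidden: int = 128, n_layers: int = 3,
                 seed: int = 0, n_features: int = N_FEATURES) -> ModelWeights:
    """Seeded He-normal initialization; a fixed seed gives identical weights."""
    rng = np.random.default_rng(seed)
    params = {}
    n_in = n_features
    for l in range(n_layers):
        Ws, b = nnet.init_linear(rng, n_in, width)
        Wn, _ = nnet.init_linear(rng, n_in, width)
        params[f"gnn{l}/Ws"] = Ws
        params[f"gnn{l}/Wn"] = Wn
        params[f"gnn{l}/b"] = b
        n_in = width
    emb_width = n_features + width
    for cls in _TERM_CLASSES:
        p = nnet.mlp2_init(rng, _ARITY[cls] * emb_width, hidden, width)
        for k, v in p.items():
            params[f"pool_{cls}/{k}"] = v
        r = nnet.mlp2_init(rng, width, hidden, _N_OUT[cls], out_std=0.01,
                           out_bias=_readout_bias(cls))
        for k, v in r.items():
            params[f"read_{cls}/{k}"] = v
        # zero-initialized linear bypass: keeps the initial outputs at the
        # priors while giving every readout a convex, always-available path
        # for separating chemical environments from epoch one
        params[f"read_{cls}/Wskip"] = np.zeros((width, _N_OUT[cls]))
    c = nnet.mlp2_init(rng, emb_width, hidden, 2, out_std=0.01,
                       out_bias=[0.0, float(nnet.softplus_inv(2.0))])
    for k, v in c.items():
        params[f"charge/{k}"] = v
    params["charge/Wskip"] = np.zeros((emb_width, 2))
    hyper = {"width": width, "hidden": hidden, "n_layers": n_layers,
             "n_features": n_features, "seed": seed, "activation": "relu"}
    return ModelWeights(params=params, hyper=hyper)


def _sub(params: dict, prefix: str) -> dict:
    return {k.split("/", 1)[1]: v for k, v in params.items()
            if k.startswith(prefix + "/")}


# ---------------------------------------------------------------------------
# stage 1: atom embeddings


def embed_atoms(graph: ChemicalGraph, w: ModelWeights, return_cache=False):
    """Per-atom latent vectors; equal rows for graph-automorphic atoms.

    The embedding is the input feature vector concatenated with the output
    of the message-passing layers (a skip connection): the raw features make
    the local atom identity directly available to every downstream readout,
    while the message-passing part encodes the wider chemical environment.
    """
    if graph.node_features.shape[1] != w.hyper["n_features"]:
        raise ConfigurationError(
            f"feature width {graph.node_features.shape[1]} does not match "
            f"model ({w.hyper['n_features']})")
    n = graph.n_atoms
    A = np.zeros((n, n))
    for i, j in graph.adjacency:
        A[i, j] = 1.0
        A[j, i] = 1.0
    H = graph.node_features
    caches = []
    for l in range(w.hyper["n_layers"]):
        M = A @ H
        pre = H @ w.params[f"gnn{l}/Ws"] + M @ w.params[f"gnn{l}/Wn"] + w.params[f"gnn{l}/b"]
        out = np.maximum(pre, 0.0)
        caches.append((H, M, pre > 0.0))
        H = out
    emb = np.concatenate([graph.node_features, H], axis=1)
    if return_cache:
        return emb, (A, caches)
    return emb


def embedding_width(hyper: dict) -> int:
    return hyper["n_features"] + hyper["width"]


def _embed_backward(graph, w, cache, dEmb):
    A, caches = cache
    grads = {}
    dH = dEmb[:, w.hyper["n_features"]:]   # skip-connection part has no weights
    for l in reversed(range(w.hyper["n_layers"])):
        H_in, M, mask = caches[l]
        dpre = dH * mask
        grads[f"gnn{l}/Ws"] = H_in.T @ dpre
        grads[f"gnn{l}/Wn"] = M.T @ dpre
        grads[f"gnn{l}/b"] = dpre.sum(axis=0)
        dH = dpre @ w.params[f"gnn{l}/Ws"].T + A @ (dpre @ w.params[f"gnn{l}/Wn"].T)
    return dH, grads


# ---------------------------------------------------------------------------
# stage 2: Janossy pooling


def pool_terms(emb: np.ndarray, topo: TermTopology, w: ModelWeights,
               return_cache=False):
    """Permutation-invariant term embeddings per class."""
    D = emb.shape[1]
    out_width = w.hyper["width"]
    idx = {"bond": topo.bonds, "angle": topo.angles,
           "proper": topo.propers, "improper": topo.impropers}
    out, caches = {}, {}
    for cls in _TERM_CLASSES:
        rows = idx[cls]
        T = len(rows)
        p = _sub(w.params, f"pool_{cls}")
        if T == 0:
            out[cls] = np.zeros((0, out_width))
            caches[cls] = []
            continue
        Z = None
        cl = []
        for perm in _PERMS[cls]:
            x = emb[rows[:, list(perm)]].reshape(T, -1)
            y, cache = nnet.mlp2_forward(p, x)
            Z = y if Z is None else Z + y
            cl.append(cache)
        out[cls] = Z
        caches[cls] = cl
    if return_cache:
        return out, (idx, caches)
    return out


def _pool_backward(emb_shape, topo, w, cache, dZ: dict):
    idx, caches = cache
    dH = np.zeros(emb_shape)
    grads = {}
    for cls in _TERM_CLASSES:
        rows = idx[cls]
        p = _sub(w.params, f"pool_{cls}")
        acc = {k: np.zeros_like(v) for k, v in p.items()}
        if len(rows):
            T = len(rows)
            D = emb_shape[1]
            for perm, cl in zip(_PERMS[cls], caches[cls]):
                dx, g = nnet.mlp2_backward(p, cl, dZ[cls])
                nnet.add_into(acc, g)
                dx = dx.reshape(T, len(perm), D)
                np.add.at(dH, rows[:, list(perm)], dx)
        for k, v in acc.items():
            grads[f"pool_{cls}/{k}"] = v
    return dH, grads


# ---------------------------------------------------------------------------
# stage 3: readout and range maps


def _readout_raw(pooled: dict, w: ModelWeights, return_cache=False):
    raw, caches = {}, {}
    for cls in _TERM_CLASSES:
        p = _sub(w.params, f"read_{cls}")
        if len(pooled[cls]) == 0:
            raw[cls] = np.zeros((0, _N_OUT[cls]))
            caches[cls] = None
            continue
        y, cache = nnet.mlp2_forward(p, pooled[cls])
        raw[cls] = y + pooled[cls] @ p["Wskip"]
        caches[cls] = cache
    if return_cache:
        return raw, caches
    return raw


def _readout_backward(pooled, w, caches, draw):
    dZ, grads = {}, {}
    for cls in _TERM_CLASSES:
        p = _sub(w.params, f"read_{cls}")
        acc = {k: np.zeros_like(v) for k, v in p.items()}
        if caches[cls] is None:
            dZ[cls] = np.zeros_like(pooled[cls])
        else:
            dZ[cls], g = nnet.mlp2_backward(p, caches[cls], draw[cls])
            nnet.add_into(acc, g)
            acc["Wskip"] += pooled[cls].T @ draw[cls]
            dZ[cls] = dZ[cls] + draw[cls] @ p["Wskip"].T
        for k, v in acc.items():
            grads[f"read_{cls}/{k}"] = v
    return dZ, grads


def apply_valence_maps(raw: dict) -> dict:
    """Map raw readout outputs into physically-ranged valence parameters."""
    out = {}
    k_bond = KR_SCALE * nnet.softplus(raw["bond"][:, 0]) + K_FLOOR
    p_bond = KR0_SCALE * nnet.softplus(raw["bond"][:, 1]) + P_FLOOR  # K * r0
    out["bond_k"] = k_bond
    out["bond_r0"] = p_bond / k_bond
    k_angle = KTH_SCALE * nnet.softplus(raw["angle"][:, 0]) + K_FLOOR
    p_angle = KTH0_SCALE * nnet.softplus(raw["angle"][:, 1]) + P_FLOOR  # K * theta0
    out["angle_k"] = k_angle
    # the ratio is squashed through a sigmoid that is ~identity over the
    # physical range (~1.5-2.3 rad) but guarantees theta0 in (0, pi); the
    # clip only guards float saturation far outside that range, where the
    # sigmoid gradient is zero anyway
    sg = nnet.sigmoid((p_angle / k_angle - np.pi / 2) * (4.0 / np.pi))
    out["angle_theta0"] = np.pi * np.clip(sg, 1e-9, 1.0 - 1e-9)
    out["proper_k"] = TOR_SCALE * raw["proper"]
    out["improper_k"] = TOR_SCALE * raw["improper"]
    return out


def valence_map_backward(raw: dict, dval: dict) -> dict:
    """Chain dL/d(parameters) back to dL/d(raw readout outputs)."""
    draw = {cls: np.zeros_like(raw[cls]) for cls in _TERM_CLASSES}
    sp = nnet.sigmoid  # d softplus(x)/dx = sigmoid(x)

    # bond: K = f(a), P = g(b), r0 = P/K
    k_bond = KR_SCALE * nnet.softplus(raw["bond"][:, 0]) + K_FLOOR
    p_bond = KR0_SCALE * nnet.softplus(raw["bond"][:, 1]) + P_FLOOR
    dK = dval["bond_k"] + dval["bond_r0"] * (-p_bond / k_bond ** 2)
    dP = dval["bond_r0"] / k_bond
    draw["bond"][:, 0] = dK * KR_SCALE * sp(raw["bond"][:, 0])
    draw["bond"][:, 1] = dP * KR0_SCALE * sp(raw["bond"][:, 1])

    k_angle = KTH_SCALE * nnet.softplus(raw["angle"][:, 0]) + K_FLOOR
    p_angle = KTH0_SCALE * nnet.softplus(raw["angle"][:, 1]) + P_FLOOR
    sg = nnet.sigmoid((p_angle / k_angle - np.pi / 2) * (4.0 / np.pi))
    dratio = dval["angle_theta0"] * 4.0 * sg * (1.0 - sg)  # d theta0/d(P/K)
    dK = dval["angle_k"] + dratio * (-p_angle / k_angle ** 2)
    dP = dratio / k_angle
    draw["angle"][:, 0] = dK * KTH_SCALE * sp(raw["angle"][:, 0])
    draw["angle"][:, 1] = dP * KTH0_SCALE * sp(raw["angle"][:, 1])

    draw["proper"] = dval["proper_k"] * TOR_SCALE
    draw["improper"] = dval["improper_k"] * TOR_SCALE
    return draw


# ---------------------------------------------------------------------------
# full network forward/backward (used by training)


@dataclass
class NetForward:
    """Forward activations and caches for one molecule."""

    graph: ChemicalGraph
    topo: TermTopology
    emb: np.ndarray
    pooled: dict
    raw: dict                 # raw valence readouts per class
    valence: dict             # mapped valence parameters
    charge_raw: np.ndarray    # (n_atoms, 2) raw charge-head output
    emb_cache: tuple = field(repr=False, default=None)
    pool_cache: tuple = field(repr=False, default=None)
    read_cache: dict = field(repr=False, default=None)
    charge_cache: tuple = field(repr=False, default=None)


def network_forward(graph: ChemicalGraph, topo: TermTopology,
                    w: ModelWeights) -> NetForward:
    emb, emb_cache = embed_atoms(graph, w, return_cache=True)
    pooled, pool_cache = pool_terms(emb, topo, w, return_cache=True)
    raw, read_cache = _readout_raw(pooled, w, return_cache=True)
    cp = _sub(w.params, "charge")
    charge_raw, charge_cache = nnet.mlp2_forward(cp, emb)
    charge_raw = charge_raw + emb @ cp["Wskip"]
    return NetForward(graph=graph, topo=topo, emb=emb, pooled=pooled, raw=raw,
                      valence=apply_valence_maps(raw), charge_raw=charge_raw,
                      emb_cache=emb_cache, pool_cache=pool_cache,
                      read_cache=read_cache, charge_cache=charge_cache)


def network_backward(w: ModelWeights, fwd: NetForward, draw: dict,
                     dcharge_raw: np.ndarray) -> dict:
    """Backpropagate term-readout and charge-head gradients to all weights.

    ``draw`` holds dL/d(raw valence readouts) per class; ``dcharge_raw`` is
    dL/d(charge head raw output). Returns a flat gradient dict covering every
    learnable tensor.
    """
    dZ, g_read = _readout_backward(fwd.pooled, w, fwd.read_cache, draw)
    dH, g_pool = _pool_backward(fwd.emb.shape, fwd.topo, w, fwd.pool_cache, dZ)
    cp = _sub(w.params, "charge")
    dH_c, g_charge = nnet.mlp2_backward(cp, fwd.charge_cache, dcharge_raw)
    g_charge["Wskip"] = fwd.emb.T @ dcharge_raw
    dH += dH_c + dcharge_raw @ cp["Wskip"].T
    _, g_gnn = _embed_backward(fwd.graph, w, fwd.emb_cache, dH)
    grads = {}
    grads.update(g_read)
    grads.update(g_pool)
    grads.update({f"charge/{k}": v for k, v in g_charge.items()})
    grads.update(g_gnn)
    return grads


# ---------------------------------------------------------------------------
# Lennard-Jones reference table and the assembled parameter set


class LennardJonesTable:
    """Fixed nonbonded sigma/epsilon, keyed by a reference typing function.

    ``entries`` maps a hashable atom-type key to ``(sigma, epsilon)``;
    ``key_fn(molecule)`` returns the per-atom keys. These parameters are
    copied verbatim into every parameter set, never learned.
    """

    def __init__(self, entries: dict, key_fn):
        self.entries = dict(entries)
        self.key_fn = key_fn

    def lookup(self, mol: Molecule):
        keys = self.key_fn(mol)
        sigma = np.empty(mol.n_atoms)
        epsilon = np.empty(mol.n_atoms)
        for i, key in enumerate(keys):
            if key not in self.entries:
                raise ParametrizationError(
                    f"no Lennard-Jones entry for atom {i} "
                    f"({mol.atoms[i][0]}, type key {key})")
            sigma[i], epsilon[i] = self.entries[key]
        return sigma, epsilon


@dataclass
class MMParameterSet:
    """All Class I force-field parameters for one molecule.

    Harmonic terms use the 1/2 K (x-x0)^2 convention; torsion amplitudes
    multiply (1 + cos(n phi)) with phase 0. Units: kcal/mol, Å, rad, e.
    """

    n_atoms: int
    net_charge: int
    bond_idx: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angle_idx: np.ndarray
    angle_k: np.ndarray
    angle_theta0: np.ndarray
    proper_idx: np.ndarray
    proper_k: np.ndarray      # (P, 6), n = 1..6
    improper_idx: np.ndarray  # (I, 4) as (central, a, b, d)
    improper_k: np.ndarray    # (I, 2), n = 1,2
    q: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray

    def validate(self):
        assert np.all(self.bond_k > 0) and np.all(self.angle_k > 0)
        assert np.all(self.bond_r0 > 0)
        assert np.all((self.angle_theta0 > 0) & (self.angle_theta0 < np.pi))
        assert np.all(np.isfinite(self.proper_k)) and np.all(np.isfinite(self.improper_k))
        assert abs(self.q.sum() - self.net_charge) <= 1e-10

    _ARRAYS = ("bond_idx", "bond_k", "bond_r0", "angle_idx", "angle_k",
               "angle_theta0", "proper_idx", "proper_k", "improper_idx",
               "improper_k", "q", "sigma", "epsilon")

    def to_json(self) -> str:
        payload = {"schema": "graphff-parameters-1",
                   "units": {"energy": "kcal/mol", "length": "angstrom",
                             "angle": "rad", "charge": "e"},
                   "n_atoms": self.n_atoms, "net_charge": self.net_charge}
        for name in self._ARRAYS:
            payload[name] = getattr(self, name).tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MMParameterSet":
        d = json.loads(text)
        kwargs = {"n_atoms": d["n_atoms"], "net_charge": d["net_charge"]}
        for name in cls._ARRAYS:
            dtype = np.int64 if name.endswith("_idx") else np.float64
            arr = np.array(d[name], dtype=dtype)
            if arr.size == 0:
                width = {"bond_idx": 2, "angle_idx": 3, "proper_idx": 4,
                         "improper_idx": 4, "proper_k": 6, "improper_k": 2}.get(name)
                if width:
                    arr = arr.reshape(0, width)
            kwargs[name] = arr
        return cls(**kwargs)


def readout_parameters(fwd: NetForward, mol: Molecule, w: ModelWeights,
                       lj_table: LennardJonesTable) -> MMParameterSet:
    """Assemble an :class:`MMParameterSet` from a network forward pass."""
    from .charges import charge_head_maps, equilibrate

    sigma, epsilon = lj_table.lookup(mol)
    e, s = charge_head_maps(fwd.charge_raw)
    q = equilibrate(e, s, mol.net_charge)
    val = fwd.valence
    params = MMParameterSet(
        n_atoms=mol.n_atoms, net_charge=mol.net_charge,
        bond_idx=fwd.topo.bonds, bond_k=val["bond_k"], bond_r0=val["bond_r0"],
        angle_idx=fwd.topo.angles, angle_k=val["angle_k"],
        angle_theta0=val["angle_theta0"],
        proper_idx=fwd.topo.propers, proper_k=val["proper_k"],
        improper_idx=fwd.topo.impropers, improper_k=val["improper_k"],
        q=q, sigma=sigma, epsilon=epsilon)
    params.validate()
    return params


def parametrize(mol: Molecule, w: ModelWeights,
                lj_table: LennardJonesTable) -> MMParameterSet:
    """Assign all MM parameters for one molecular species.

    Performed once per species; the result is geometry-independent and can
    be cached and reused for any conformation.
    """
    graph = featurize(mol)
    topo = enumerate_terms(graph)
    fwd = network_forward(graph, topo, w)
    return readout_parameters(fwd, mol, w, lj_table)
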