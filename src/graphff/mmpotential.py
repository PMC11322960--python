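"""Class I molecular-mechanics energies, analytic forces, and minimization.

The potential is the standard Class I form: harmonic bonds and angles
(1/2 K (x - x0)^2 convention), periodic proper torsions K_n (1 + cos n*phi)
with phase 0 for n = 1..6, improper torsions of the same form with n = 1,2
summed over the three cyclic outer-atom arrangements at each 3-connected
central atom, 12-6 Lennard-Jones with Lorentz-Berthelot combination, and
fixed-charge Coulomb electrostatics. Nonbonded evaluation is gas-phase and
cutoff-free; 1-2 and 1-3 pairs are excluded and 1-4 pairs scaled.

Geometry factors (distances, angles, dihedrals and their Cartesian
gradients) depend only on coordinates, not on parameters, so they are
precomputed once per conformer batch in :class:`GeometryCache`. Training
re-uses a cache across epochs; energies, forces, and parameter gradients
are then plain tensor contractions against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .model import MMParameterSet
from .units import COULOMB_CONSTANT, SCALE14_COULOMB, SCALE14_LJ

__all__ = ["Conformation", "EnergyBreakdown", "NonbondedSettings",
           "GeometryCache", "energy", "forces", "minimize",
           "MinimizationError", "dihedral_angles"]

_PROPER_NS = np.arange(1, 7, dtype=np.float64)     # periodicities n = 1..6
_IMPROPER_NS = np.arange(1, 3, dtype=np.float64)   # periodicities n = 1,2


class MinimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Conformation:
    """Cartesian coordinates in Å, shape (n_atoms, 3)."""

    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "coords",
                           np.asarray(self.coords, dtype=np.float64))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    proper: float
    improper: float
    lj: float
    coulomb: float

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.proper + self.improper
                + self.lj + self.coulomb)


@dataclass(frozen=True)
class NonbondedSettings:
    scale14_coulomb: float = SCALE14_COULOMB
    scale14_lj: float = SCALE14_LJ
    coulomb_constant: float = COULOMB_CONSTANT


# ---------------------------------------------------------------------------
# geometry primitives (batched over conformers, leading axis C)


def _bond_geometry(X, idx):
    vec = X[:, idx[:, 0], :] - X[:, idx[:, 1], :]
    r = np.linalg.norm(vec, axis=-1)
    u = vec / r[..., None]
    return r, u


def _angle_geometry(X, idx):
    """Angles theta(i,j,k) and gradients wrt the three atoms."""
    u = X[:, idx[:, 0], :] - X[:, idx[:, 1], :]
    v = X[:, idx[:, 2], :] - X[:, idx[:, 1], :]
    ru = np.linalg.norm(u, axis=-1)
    rv = np.linalg.norm(v, axis=-1)
    cos = np.sum(u * v, axis=-1) / (ru * rv)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-12, None))
    gi = (cos[..., None] * u / ru[..., None] - v / rv[..., None]) / (ru * sin)[..., None]
    gk = (cos[..., None] * v / rv[..., None] - u / ru[..., None]) / (rv * sin)[..., None]
    gj = -(gi + gk)
    return theta, gi, gj, gk


def _dihedral_geometry(X, idx):
    """Dihedrals phi(i,j,k,l), IUPAC sign, range (-pi, pi], with gradients."""
    xi, xj = X[:, idx[:, 0], :], X[:, idx[:, 1], :]
    xk, xl = X[:, idx[:, 2], :], X[:, idx[:, 3], :]
    b1 = xj - xi
    b2 = xk - xj
    b3 = xl - xk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / nb2
    x = np.sum(n1 * n2, axis=-1)
    phi = np.arctan2(y, x)
    n1sq = np.sum(n1 * n1, axis=-1)
    n2sq = np.sum(n2 * n2, axis=-1)
    gi = -(nb2 / n1sq)[..., None] * n1
    gl = (nb2 / n2sq)[..., None] * n2
    t = (np.sum(b1 * b2, axis=-1) / nb2 ** 2)[..., None]
    s = (np.sum(b3 * b2, axis=-1) / nb2 ** 2)[..., None]
    gj = -(1.0 + t) * gi + s * gl
    gk = t * gi - (1.0 + s) * gl
    return phi, gi, gj, gk, gl


def dihedral_angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Dihedral angles for (n,4) index rows on a single conformation."""
    if len(idx) == 0:
        return np.zeros(0)
    phi, *_ = _dihedral_geometry(coords[None], np.asarray(idx))
    return phi[0]


def _improper_arrangements(improper_idx: np.ndarray) -> np.ndarray:
    """Dihedral index rows for the 3 cyclic outer arrangements per improper.

    Rows of ``improper_idx`` are (c, a, b, d); each arrangement (x, c, y, z)
    is evaluated as an ordinary dihedral. Arrangements are improper-major.
    """
    if len(improper_idx) == 0:
        return np.zeros((0, 4), dtype=np.int64)
    c, a, b, d = (improper_idx[:, 0], improper_idx[:, 1],
                  improper_idx[:, 2], improper_idx[:, 3])
    arrs = np.stack([
        np.stack([a, c, b, d], axis=1),
        np.stack([b, c, d, a], axis=1),
        np.stack([d, c, a, b], axis=1),
    ], axis=1)  # (I, 3, 4)
    return arrs.reshape(-1, 4)


def topological_distances(n_atoms: int, bond_idx: np.ndarray,
                          max_depth: int = 3) -> np.ndarray:
    """Bond-path distances up to ``max_depth`` (BFS); farther pairs get -1."""
    nbrs = [[] for _ in range(n_atoms)]
    for i, j in bond_idx:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    dist = -np.ones((n_atoms, n_atoms), dtype=np.int64)
    for src in range(n_atoms):
        dist[src, src] = 0
        frontier = [src]
        for depth in range(1, max_depth + 1):
            nxt = []
            for a in frontier:
                for b in nbrs[a]:
                    if dist[src, b] < 0:
                        dist[src, b] = depth
                        nxt.append(b)
            frontier = nxt
    return dist


def nonbonded_pairs(n_atoms: int, bond_idx: np.ndarray,
                    nb: NonbondedSettings):
    """All i<j pairs beyond 1-3, with per-pair LJ/Coulomb scale factors.

    The minimum bond-path distance decides the category (ring-closure pairs
    use the shorter path, matching common MM engine behavior).
    """
    dist = topological_distances(n_atoms, bond_idx, max_depth=3)
    pairs, s_lj, s_q = [], [], []
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            d = dist[i, j]
            if d in (1, 2):
                continue
            if d == 3:
                pairs.append((i, j))
                s_lj.append(nb.scale14_lj)
                s_q.append(nb.scale14_coulomb)
            else:
                pairs.append((i, j))
                s_lj.append(1.0)
                s_q.append(1.0)
    if not pairs:
        return (np.zeros((0, 2), dtype=np.int64), np.zeros(0), np.zeros(0))
    return np.array(pairs, dtype=np.int64), np.array(s_lj), np.array(s_q)


# ---------------------------------------------------------------------------
# geometry cache


class GeometryCache:
    """Parameter-independent geometry factors for a batch of conformers."""

    def __init__(self, params: MMParameterSet, coords: np.ndarray,
                 nb: NonbondedSettings = NonbondedSettings(), pairs=None):
        X = np.asarray(coords, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != params.n_atoms:
            raise ValueError(
                f"coordinate array has {X.shape[1]} atoms, parameters have "
                f"{params.n_atoms}")
        self.n_conf, self.n_atoms = X.shape[0], X.shape[1]
        self.nb = nb

        self.bond_idx = params.bond_idx
        if len(self.bond_idx):
            self.bond_r, self.bond_u = _bond_geometry(X, self.bond_idx)
        else:
            self.bond_r = np.zeros((self.n_conf, 0))
            self.bond_u = np.zeros((self.n_conf, 0, 3))

        self.angle_idx = params.angle_idx
        if len(self.angle_idx):
            self.theta, self.ang_gi, self.ang_gj, self.ang_gk = \
                _angle_geometry(X, self.angle_idx)
        else:
            self.theta = np.zeros((self.n_conf, 0))
            self.ang_gi = self.ang_gj = self.ang_gk = np.zeros((self.n_conf, 0, 3))

        self.proper_idx = params.proper_idx
        if len(self.proper_idx):
            phi, gi, gj, gk, gl = _dihedral_geometry(X, self.proper_idx)
            self.proper_phi = phi
            self.proper_g = np.stack([gi, gj, gk, gl], axis=2)  # (C,P,4,3)
        else:
            self.proper_phi = np.zeros((self.n_conf, 0))
            self.proper_g = np.zeros((self.n_conf, 0, 4, 3))

        self.improper_arr_idx = _improper_arrangements(params.improper_idx)
        if len(self.improper_arr_idx):
            psi, gi, gj, gk, gl = _dihedral_geometry(X, self.improper_arr_idx)
            self.improper_psi = psi
            self.improper_g = np.stack([gi, gj, gk, gl], axis=2)
        else:
            self.improper_psi = np.zeros((self.n_conf, 0))
            self.improper_g = np.zeros((self.n_conf, 0, 4, 3))

        if pairs is None:
            pairs = nonbonded_pairs(params.n_atoms, params.bond_idx, nb)
        self.pair_idx, self.pair_slj, self.pair_sq = pairs
        if len(self.pair_idx):
            self.pair_r, self.pair_u = _bond_geometry(X, self.pair_idx)
        else:
            self.pair_r = np.zeros((self.n_conf, 0))
            self.pair_u = np.zeros((self.n_conf, 0, 3))


# ---------------------------------------------------------------------------
# energies


def _lj_pair_params(params, pair_idx):
    si = params.sigma[pair_idx[:, 0]]
    sj = params.sigma[pair_idx[:, 1]]
    ei = params.epsilon[pair_idx[:, 0]]
    ej = params.epsilon[pair_idx[:, 1]]
    return 0.5 * (si + sj), np.sqrt(ei * ej)  # Lorentz-Berthelot


def energy_components(params: MMParameterSet, cache: GeometryCache):
    """Per-conformer energy components, each an array of shape (C,)."""
    C = cache.n_conf
    comp = {}
    db = cache.bond_r - params.bond_r0
    comp["bond"] = 0.5 * (params.bond_k * db * db).sum(axis=1) if db.size else np.zeros(C)
    da = cache.theta - params.angle_theta0
    comp["angle"] = 0.5 * (params.angle_k * da * da).sum(axis=1) if da.size else np.zeros(C)

    if cache.proper_phi.size:
        cosn = np.cos(cache.proper_phi[..., None] * _PROPER_NS)
        comp["proper"] = (params.proper_k * (1.0 + cosn)).sum(axis=(1, 2))
    else:
        comp["proper"] = np.zeros(C)

    if cache.improper_psi.size:
        k_rep = np.repeat(params.improper_k, 3, axis=0)  # improper-major
        cosn = np.cos(cache.improper_psi[..., None] * _IMPROPER_NS)
        comp["improper"] = (k_rep * (1.0 + cosn)).sum(axis=(1, 2))
    else:
        comp["improper"] = np.zeros(C)

    if cache.pair_r.size:
        sig, eps = _lj_pair_params(params, cache.pair_idx)
        sr6 = (sig / cache.pair_r) ** 6
        comp["lj"] = (cache.pair_slj * 4.0 * eps * (sr6 * sr6 - sr6)).sum(axis=1)
        qq = params.q[cache.pair_idx[:, 0]] * params.q[cache.pair_idx[:, 1]]
        comp["coulomb"] = (cache.nb.coulomb_constant * cache.pair_sq * qq
                           / cache.pair_r).sum(axis=1)
    else:
        comp["lj"] = np.zeros(C)
        comp["coulomb"] = np.zeros(C)
    return comp


def energy_total(params: MMParameterSet, cache: GeometryCache) -> np.ndarray:
    comp = energy_components(params, cache)
    return sum(comp.values())


def energy(params: MMParameterSet, conf: Conformation,
           nb: NonbondedSettings = NonbondedSettings()) -> EnergyBreakdown:
    """Energy breakdown for a single conformation (kcal/mol)."""
    cache = GeometryCache(params, conf.coords, nb)
    comp = energy_components(params, cache)
    out = EnergyBreakdown(**{k: float(v[0]) for k, v in comp.items()})
    if not np.isfinite(out.total):
        bad = [k for k, v in comp.items() if not np.isfinite(v[0])]
        raise FloatingPointError(f"non-finite energy in terms: {bad}")
    return out


# ---------------------------------------------------------------------------
# forces


def _scatter_add(F, atom_idx, contrib):
    """F[c, atom_idx[t], :] += contrib[c, t, :] with duplicate-safe adds."""
    Fv = F.transpose(1, 0, 2)          # view (N, C, 3)
    np.add.at(Fv, atom_idx, contrib.transpose(1, 0, 2))


def forces_batch(params: MMParameterSet, cache: GeometryCache) -> np.ndarray:
    """Analytic forces -dU/dx, shape (C, N, 3), kcal/mol/Å."""
    F = np.zeros((cache.n_conf, cache.n_atoms, 3))

    if cache.bond_r.size:
        fb = -(params.bond_k * (cache.bond_r - params.bond_r0))  # dE/dr with sign
        contrib = fb[..., None] * cache.bond_u
        _scatter_add(F, cache.bond_idx[:, 0], contrib)
        _scatter_add(F, cache.bond_idx[:, 1], -contrib)

    if cache.theta.size:
        fa = -(params.angle_k * (cache.theta - params.angle_theta0))
        for pos, g in ((0, cache.ang_gi), (1, cache.ang_gj), (2, cache.ang_gk)):
            _scatter_add(F, cache.angle_idx[:, pos], fa[..., None] * g)

    if cache.proper_phi.size:
        sinn = np.sin(cache.proper_phi[..., None] * _PROPER_NS)
        ft = (params.proper_k * _PROPER_NS * sinn).sum(axis=-1)  # = -dE/dphi
        for pos in range(4):
            _scatter_add(F, cache.proper_idx[:, pos],
                         ft[..., None] * cache.proper_g[:, :, pos, :])

    if cache.improper_psi.size:
        k_rep = np.repeat(params.improper_k, 3, axis=0)
        sinn = np.sin(cache.improper_psi[..., None] * _IMPROPER_NS)
        ft = (k_rep * _IMPROPER_NS * sinn).sum(axis=-1)
        for pos in range(4):
            _scatter_add(F, cache.improper_arr_idx[:, pos],
                         ft[..., None] * cache.improper_g[:, :, pos, :])

    if cache.pair_r.size:
        sig, eps = _lj_pair_params(params, cache.pair_idx)
        r = cache.pair_r
        sr6 = (sig / r) ** 6
        dE_dr = cache.pair_slj * 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        qq = params.q[cache.pair_idx[:, 0]] * params.q[cache.pair_idx[:, 1]]
        dE_dr += -cache.nb.coulomb_constant * cache.pair_sq * qq / r ** 2
        contrib = -dE_dr[..., None] * cache.pair_u
        _scatter_add(F, cache.pair_idx[:, 0], contrib)
        _scatter_add(F, cache.pair_idx[:, 1], -contrib)

    return F


def forces(params: MMParameterSet, conf: Conformation,
           nb: NonbondedSettings = NonbondedSettings()) -> np.ndarray:
    """Analytic forces for one conformation, shape (N, 3)."""
    cache = GeometryCache(params, conf.coords, nb)
    return forces_batch(params, cache)[0]


# ---------------------------------------------------------------------------
# gradients of (energy, force) losses wrt parameters


def parameter_gradients(params: MMParameterSet, cache: GeometryCache,
                        dE: np.ndarray, dF: np.ndarray | None) -> dict:
    """Chain per-conformer adjoints to parameter gradients.

    ``dE`` is dL/dU per conformer, shape (C,); ``dF`` is dL/dF, shape
    (C, N, 3) or None. Returns gradients for every learnable parameter
    array (bond_k, bond_r0, angle_k, angle_theta0, proper_k, improper_k, q).
    LJ sigma/epsilon are fixed, so no gradients are produced for them.
    """
    g = {}
    dE = np.asarray(dE, dtype=np.float64)

    def gather(idx_col):
        return dF[:, idx_col, :] if dF is not None else None

    # bonds
    if cache.bond_r.size:
        delta = cache.bond_r - params.bond_r0
        gk = (dE[:, None] * 0.5 * delta * delta).sum(axis=0)
        gr0 = (dE[:, None] * (-params.bond_k * delta)).sum(axis=0)
        if dF is not None:
            s = ((gather(cache.bond_idx[:, 0]) - gather(cache.bond_idx[:, 1]))
                 * cache.bond_u).sum(axis=-1)          # (C,B)
            gk += (-delta * s).sum(axis=0)
            gr0 += params.bond_k * s.sum(axis=0)
        g["bond_k"], g["bond_r0"] = gk, gr0
    else:
        g["bond_k"] = np.zeros(0)
        g["bond_r0"] = np.zeros(0)

    # angles
    if cache.theta.size:
        delta = cache.theta - params.angle_theta0
        gk = (dE[:, None] * 0.5 * delta * delta).sum(axis=0)
        gt0 = (dE[:, None] * (-params.angle_k * delta)).sum(axis=0)
        if dF is not None:
            s = np.zeros_like(delta)
            for pos, gg in ((0, cache.ang_gi), (1, cache.ang_gj), (2, cache.ang_gk)):
                s += (gather(cache.angle_idx[:, pos]) * gg).sum(axis=-1)
            gk += (-delta * s).sum(axis=0)
            gt0 += params.angle_k * s.sum(axis=0)
        g["angle_k"], g["angle_theta0"] = gk, gt0
    else:
        g["angle_k"] = np.zeros(0)
        g["angle_theta0"] = np.zeros(0)

    # proper torsions
    if cache.proper_phi.size:
        cosn = np.cos(cache.proper_phi[..., None] * _PROPER_NS)
        gK = (dE[:, None, None] * (1.0 + cosn)).sum(axis=0)
        if dF is not None:
            s = np.zeros_like(cache.proper_phi)
            for pos in range(4):
                s += (gather(cache.proper_idx[:, pos])
                      * cache.proper_g[:, :, pos, :]).sum(axis=-1)
            sinn = np.sin(cache.proper_phi[..., None] * _PROPER_NS)
            gK += (s[..., None] * _PROPER_NS * sinn).sum(axis=0)
        g["proper_k"] = gK
    else:
        g["proper_k"] = np.zeros((0, len(_PROPER_NS)))

    # improper torsions (sum the three arrangements back onto each improper)
    if cache.improper_psi.size:
        cosn = np.cos(cache.improper_psi[..., None] * _IMPROPER_NS)
        gK_arr = (dE[:, None, None] * (1.0 + cosn)).sum(axis=0)
        if dF is not None:
            s = np.zeros_like(cache.improper_psi)
            for pos in range(4):
                s += (gather(cache.improper_arr_idx[:, pos])
                      * cache.improper_g[:, :, pos, :]).sum(axis=-1)
            sinn = np.sin(cache.improper_psi[..., None] * _IMPROPER_NS)
            gK_arr += (s[..., None] * _IMPROPER_NS * sinn).sum(axis=0)
        g["improper_k"] = gK_arr.reshape(-1, 3, len(_IMPROPER_NS)).sum(axis=1)
    else:
        g["improper_k"] = np.zeros((0, len(_IMPROPER_NS)))

    # charges (Coulomb only; LJ carries no learnable parameters)
    gq = np.zeros(params.n_atoms)
    if cache.pair_r.size:
        i, j = cache.pair_idx[:, 0], cache.pair_idx[:, 1]
        ke = cache.nb.coulomb_constant * cache.pair_sq
        de_pair = (dE[:, None] * (ke / cache.pair_r)).sum(axis=0)  # d/d(qi*qj)
        if dF is not None:
            w = ((gather(i) - gather(j)) * cache.pair_u).sum(axis=-1)
            de_pair += (w * ke / cache.pair_r ** 2).sum(axis=0)
        np.add.at(gq, i, de_pair * params.q[j])
        np.add.at(gq, j, de_pair * params.q[i])
    g["q"] = gq
    return g


# ---------------------------------------------------------------------------
# minimization


def minimize(params: MMParameterSet, conf: Conformation,
             tol: float = 1e-3, max_iter: int = 2000,
             nb: NonbondedSettings = NonbondedSettings()) -> Conformation:
    """Local minimization to max-|force| <= tol (kcal/mol/Å); deterministic."""
    n = params.n_atoms

    def fun(x):
        c = Conformation(x.reshape(n, 3))
        cache = GeometryCache(params, c.coords, nb)
        e = float(energy_total(params, cache)[0])
        grad = -forces_batch(params, cache)[0]
        return e, grad.ravel()

    x = conf.coords.ravel()
    nit = 0
    for _ in range(4):  # L-BFGS restarts clear stale curvature pairs
        res = _scipy_minimize(fun, x, jac=True, method="L-BFGS-B",
                              options={"maxiter": max_iter, "ftol": 1e-16,
                                       "gtol": tol * 1e-2})
        x = res.x
        nit += res.nit
        out = Conformation(x.reshape(n, 3))
        fmax = np.abs(forces(params, out, nb)).max()
        if fmax <= tol:
            return out
    raise MinimizationError(
        f"minimization did not reach tolerance: max |force| = {fmax:.3e} "
        f"kcal/mol/Å after {nit} iterations")
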