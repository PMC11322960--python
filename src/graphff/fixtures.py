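"""Synthetic-data engine: a reference MM force field with known ground truth,
an independently coded energy oracle, and a Boltzmann conformer sampler.

The generator stands in for a quantum-chemistry corpus. Ground truth is a
Class I MM reference force field whose parameters are an exact function of a
small atom-typing table, so the learning pipeline's recovery error measures
the pipeline alone: a perfect model can reproduce the reference surface
exactly. Reference typing is deliberately coarser than the network's node
features (element, heavy degree, H count, any-ring membership) so every
ground-truth assignment is resolvable by the network.

Per-type parameters are generated once from a fixed internal seed by hashing
the type key, independent of which molecules are present; all values lie in
physically sensible ranges (bond K 300-700 kcal/mol/Å², r0 from covalent
radii, angle K 60-140 kcal/mol/rad², torsion amplitudes ~1 kcal/mol).

Conformers are sampled by Metropolis Monte Carlo at a 500 K acceptance
temperature (Cartesian displacements plus rotatable-torsion moves) started
from the relaxed geometry, which guarantees both low-energy structures and a
substantial high-energy population. Stored energies and gradients come from
:func:`oracle_energy`, a deliberately simple loop-based implementation that
shares no energy code with :mod:`graphff.mmpotential` and serves as the
independent cross-check for it.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
from rdkit.Chem import AllChem
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .chemgraph import Molecule, enumerate_terms, featurize, parse_molecule
from .data import MoleculeDataset, MoleculeEntry
from .model import LennardJonesTable, MMParameterSet
from .mmpotential import (GeometryCache, NonbondedSettings, energy_total,
                          forces_batch, nonbonded_pairs)
from .units import BOLTZMANN_KCALMOL, COULOMB_CONSTANT, SCALE14_COULOMB, SCALE14_LJ

__all__ = ["ReferenceForceField", "oracle_energy", "build_fixture_set",
           "sample_conformers", "atom_type_keys", "FIXTURE_SMILES"]

SAMPLER_TEMPERATURE_K = 500.0

#: fixture chemistry: homolog pairs per functional family spanning alkanes,
#: cycloalkanes, alkenes/dienes, aromatics, phenols, N/O heteroaromatics,
#: alcohols, ethers, amines, aldehydes, ketones, and charged species
#: (carboxylates -1, alkylammonium +1), so most chemical environments occur
#: in more than one molecule
FIXTURE_SMILES = (
    "CCC", "CCCC", "CC(C)C", "CCC(C)C",
    "C1CCCC1", "C1CCCCC1",
    "CC=C", "C=CC=C", "CC=CC=C",
    "c1ccccc1", "Cc1ccccc1",
    "Oc1ccccc1", "Cc1ccc(O)cc1",
    "c1ccncc1", "Cc1ccncc1",
    "c1cc[nH]c1", "c1ccoc1",
    "CCO", "CC(C)O",
    "CCOC",
    "CCN", "CNC",
    "CC=O", "CC(C)=O",
    "CC(=O)[O-]", "CCC(=O)[O-]",
    "CC[NH3+]", "CCC[NH3+]",
)

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                   "P": 1.07, "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39}
_SIGMA_BASE = {"H": 2.60, "C": 3.40, "N": 3.30, "O": 3.05, "S": 3.60,
               "P": 3.75, "F": 3.00, "Cl": 3.40, "Br": 3.55, "I": 3.75}
_EPS_BASE = {"H": 0.025, "C": 0.095, "N": 0.17, "O": 0.18, "S": 0.25,
             "P": 0.22, "F": 0.15, "Cl": 0.26, "Br": 0.30, "I": 0.33}
_CHARGE_BASE = {"H": 0.07, "C": -0.05, "N": -0.40, "O": -0.45, "S": -0.20,
                "P": 0.10, "F": -0.22, "Cl": -0.15, "Br": -0.12, "I": -0.10}


def atom_type_keys(mol: Molecule):
    """Reference atom typing: (element, heavy degree, H count, in-ring)."""
    rdmol = mol.rdkit_mol()
    keys = []
    for i in range(mol.n_atoms):
        atom = rdmol.GetAtomWithIdx(i)
        heavy = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        hcount = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
        keys.append((atom.GetSymbol(), heavy, hcount, int(atom.IsInRing())))
    return keys


class ReferenceForceField:
    """Procedural ground-truth force field over the typing table above.

    Every parameter is a deterministic function of the type key(s) involved,
    drawn once from a hash-seeded generator, so the assignment is identical
    no matter which molecules are parametrized or in what order.
    """

    def __init__(self, seed: int = 20240917):
        self.seed = int(seed)

    def _rng(self, tag: str, *keys):
        h = zlib.crc32(repr((tag, keys)).encode())
        return np.random.default_rng([self.seed, h])

    # -- per-class parameter tables ----------------------------------------

    def atom_params(self, key):
        elem = key[0]
        rng = self._rng("atom", key)
        sigma = _SIGMA_BASE[elem] + rng.uniform(-0.10, 0.10)
        eps = _EPS_BASE[elem] * rng.uniform(0.8, 1.25)
        base_q = _CHARGE_BASE[elem] + rng.uniform(-0.06, 0.06)
        return {"sigma": sigma, "epsilon": eps, "base_charge": base_q}

    def bond_params(self, key_i, key_j):
        ki, kj = sorted([key_i, key_j])
        rng = self._rng("bond", ki, kj)
        r0 = (_COVALENT_RADII[ki[0]] + _COVALENT_RADII[kj[0]]
              + rng.uniform(-0.04, 0.04))
        k = rng.uniform(300.0, 700.0)
        return k, r0

    def angle_params(self, key_central):
        rng = self._rng("angle", key_central)
        degree = key_central[1] + key_central[2]
        theta_base = {2: 110.0, 3: 118.0, 4: 109.47}.get(degree, 109.47)
        theta0 = math.radians(theta_base + rng.uniform(-3.0, 3.0))
        k = rng.uniform(60.0, 140.0)
        return k, theta0

    def proper_params(self, key_j, key_k):
        kj, kk = sorted([key_j, key_k])
        rng = self._rng("proper", kj, kk)
        amps = np.zeros(6)
        amps[:3] = rng.uniform(-1.2, 1.2, size=3)
        return amps

    def improper_params(self, key_central):
        rng = self._rng("improper", key_central)
        return np.array([rng.uniform(-0.5, 0.5), rng.uniform(-3.0, -0.3)])

    # -- per-molecule assignment -------------------------------------------

    def target_charges(self, mol: Molecule) -> np.ndarray:
        """Per-type base charges shifted uniformly to the net charge."""
        keys = atom_type_keys(mol)
        q = np.array([self.atom_params(k)["base_charge"] for k in keys])
        q += (mol.net_charge - q.sum()) / mol.n_atoms
        return q

    def parameters_for(self, mol: Molecule) -> MMParameterSet:
        keys = atom_type_keys(mol)
        topo = enumerate_terms(featurize(mol))
        bond_k = np.zeros(len(topo.bonds))
        bond_r0 = np.zeros(len(topo.bonds))
        for b, (i, j) in enumerate(topo.bonds):
            bond_k[b], bond_r0[b] = self.bond_params(keys[i], keys[j])
        angle_k = np.zeros(len(topo.angles))
        angle_t0 = np.zeros(len(topo.angles))
        for a, (_, j, _) in enumerate(topo.angles):
            angle_k[a], angle_t0[a] = self.angle_params(keys[j])
        proper_k = np.zeros((len(topo.propers), 6))
        for p, (_, j, k, _) in enumerate(topo.propers):
            proper_k[p] = self.proper_params(keys[j], keys[k])
        improper_k = np.zeros((len(topo.impropers), 2))
        for m, row in enumerate(topo.impropers):
            improper_k[m] = self.improper_params(keys[row[0]])
        atomp = [self.atom_params(k) for k in keys]
        return MMParameterSet(
            n_atoms=mol.n_atoms, net_charge=mol.net_charge,
            bond_idx=topo.bonds, bond_k=bond_k, bond_r0=bond_r0,
            angle_idx=topo.angles, angle_k=angle_k, angle_theta0=angle_t0,
            proper_idx=topo.propers, proper_k=proper_k,
            improper_idx=topo.impropers, improper_k=improper_k,
            q=self.target_charges(mol),
            sigma=np.array([p["sigma"] for p in atomp]),
            epsilon=np.array([p["epsilon"] for p in atomp]))

    def lj_table(self, molecules=None) -> LennardJonesTable:
        """Reference nonbonded table keyed by this force field's typing."""
        entries = {}
        mols = molecules if molecules is not None else [
            parse_molecule(s) for s in FIXTURE_SMILES]
        for mol in mols:
            for key in atom_type_keys(mol):
                p = self.atom_params(key)
                entries[key] = (p["sigma"], p["epsilon"])
        return LennardJonesTable(entries, atom_type_keys)


# ---------------------------------------------------------------------------
# independent energy oracle (loop-based; no shared energy code)


def _bfs_distances(n_atoms, bond_idx, cutoff=3):
    nbrs = [[] for _ in range(n_atoms)]
    for i, j in bond_idx:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    dist = {}
    for src in range(n_atoms):
        seen = {src: 0}
        frontier = [src]
        for depth in range(1, cutoff + 1):
            nxt = []
            for a in frontier:
                for b in nbrs[a]:
                    if b not in seen:
                        seen[b] = depth
                        nxt.append(b)
            frontier = nxt
        for b, d in seen.items():
            dist[(src, b)] = d
    return dist


def _dihedral_value_and_grad(x, rows):
    """phi and d phi/d x for one dihedral via exact product-rule derivatives
    of the atan2 arguments (linearity of b1,b2,b3 in coordinates)."""
    xi, xj, xk, xl = (x[r] for r in rows)
    b1, b2, b3 = xj - xi, xk - xj, xl - xk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = math.sqrt(b2 @ b2)
    xval = n1 @ n2
    ynum = np.cross(n1, n2) @ b2
    yval = ynum / nb2
    phi = math.atan2(yval, xval)
    denom = xval * xval + yval * yval
    grad = {}
    basis = np.eye(3)
    for pos, atom in enumerate(rows):
        g = np.zeros(3)
        for c in range(3):
            e = basis[c]
            db1 = e * ((pos == 1) - (pos == 0))
            db2 = e * ((pos == 2) - (pos == 1))
            db3 = e * ((pos == 3) - (pos == 2))
            dn1 = np.cross(db1, b2) + np.cross(b1, db2)
            dn2 = np.cross(db2, b3) + np.cross(b2, db3)
            dx = dn1 @ n2 + n1 @ dn2
            dynum = (np.cross(dn1, n2) @ b2 + np.cross(n1, dn2) @ b2
                     + np.cross(n1, n2) @ db2)
            dnb2 = (b2 @ db2) / nb2
            dy = (dynum * nb2 - ynum * dnb2) / (nb2 * nb2)
            g[c] = (xval * dy - yval * dx) / denom
        grad[atom] = grad.get(atom, 0.0) + g
    return phi, grad


def oracle_energy(params: MMParameterSet, coords: np.ndarray,
                  scale14_coulomb: float = SCALE14_COULOMB,
                  scale14_lj: float = SCALE14_LJ):
    """Slow, loop-based Class I energy and analytic gradient.

    Same physics and conventions as :mod:`graphff.mmpotential`, written as
    explicit per-term loops with independently derived gradients (angle
    gradients through d cos(theta), dihedral gradients through product-rule
    differentiation of the atan2 arguments). Returns (energy, dU/dx).
    """
    x = np.asarray(coords, dtype=np.float64)
    n = params.n_atoms
    E = 0.0
    grad = np.zeros((n, 3))

    for b, (i, j) in enumerate(params.bond_idx):
        d = x[i] - x[j]
        r = math.sqrt(d @ d)
        k, r0 = params.bond_k[b], params.bond_r0[b]
        E += 0.5 * k * (r - r0) ** 2
        g = k * (r - r0) * d / r
        grad[i] += g
        grad[j] -= g

    for a, (i, j, k_) in enumerate(params.angle_idx):
        u = x[i] - x[j]
        v = x[k_] - x[j]
        ru = math.sqrt(u @ u)
        rv = math.sqrt(v @ v)
        c = min(1.0, max(-1.0, (u @ v) / (ru * rv)))
        theta = math.acos(c)
        sin = math.sqrt(max(1.0 - c * c, 1e-12))
        K, t0 = params.angle_k[a], params.angle_theta0[a]
        E += 0.5 * K * (theta - t0) ** 2
        dci = v / (ru * rv) - c * u / ru ** 2
        dck = u / (ru * rv) - c * v / rv ** 2
        pref = -K * (theta - t0) / sin   # dE/dtheta * dtheta/dcos
        grad[i] += pref * dci
        grad[k_] += pref * dck
        grad[j] -= pref * (dci + dck)

    def torsion_term(rows, amps, ns):
        nonlocal E
        phi, dphi = _dihedral_value_and_grad(x, [int(r) for r in rows])
        dE_dphi = 0.0
        for amp, nn in zip(amps, ns):
            E += amp * (1.0 + math.cos(nn * phi))
            dE_dphi += -amp * nn * math.sin(nn * phi)
        for atom, g in dphi.items():
            grad[atom] += dE_dphi * g

    for p, rows in enumerate(params.proper_idx):
        torsion_term(rows, params.proper_k[p], range(1, 7))
    for m, row in enumerate(params.improper_idx):
        c_, a_, b_, d_ = (int(v) for v in row)
        for arrangement in ((a_, c_, b_, d_), (b_, c_, d_, a_), (d_, c_, a_, b_)):
            torsion_term(arrangement, params.improper_k[m], (1, 2))

    dist = _bfs_distances(n, params.bond_idx)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist.get((i, j), 99)
            if d in (1, 2):
                continue
            s_lj = scale14_lj if d == 3 else 1.0
            s_q = scale14_coulomb if d == 3 else 1.0
            dv = x[i] - x[j]
            r = math.sqrt(dv @ dv)
            sig = 0.5 * (params.sigma[i] + params.sigma[j])
            eps = math.sqrt(params.epsilon[i] * params.epsilon[j])
            sr6 = (sig / r) ** 6
            E += s_lj * 4.0 * eps * (sr6 * sr6 - sr6)
            dE_dr = s_lj * 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            qq = COULOMB_CONSTANT * s_q * params.q[i] * params.q[j]
            E += qq / r
            dE_dr += -qq / r ** 2
            g = dE_dr * dv / r
            grad[i] += g
            grad[j] -= g

    return E, grad


# ---------------------------------------------------------------------------
# conformer sampling


def _rotatable_bonds(mol: Molecule):
    rdmol = mol.rdkit_mol()
    out = []
    for bond in rdmol.GetBonds():
        if bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if rdmol.GetAtomWithIdx(i).GetDegree() > 1 and \
           rdmol.GetAtomWithIdx(j).GetDegree() > 1:
            out.append((i, j))
    return out


def _side_atoms(n_atoms, bond_idx, j, k):
    """Atoms reachable from k with the (j,k) edge removed, excluding k."""
    nbrs = [[] for _ in range(n_atoms)]
    for a, b in bond_idx:
        nbrs[int(a)].append(int(b))
        nbrs[int(b)].append(int(a))
    seen = {k, j}
    frontier = [k]
    side = []
    while frontier:
        nxt = []
        for a in frontier:
            for b in nbrs[a]:
                if b not in seen:
                    seen.add(b)
                    side.append(b)
                    nxt.append(b)
        frontier = nxt
    return side


def _embed_coords(mol: Molecule, seed: int) -> np.ndarray:
    rdmol = AllChem.Mol(mol.rdkit_mol())
    cid = AllChem.EmbedMolecule(rdmol, randomSeed=int(seed) % (2 ** 31 - 1),
                                useRandomCoords=False)
    if cid < 0:
        cid = AllChem.EmbedMolecule(rdmol, randomSeed=int(seed) % (2 ** 31 - 1),
                                    useRandomCoords=True)
    if cid < 0:
        raise RuntimeError(f"conformer embedding failed for {mol.identity}")
    return np.array(rdmol.GetConformer(cid).GetPositions(), dtype=np.float64)


def _relax(params: MMParameterSet, coords: np.ndarray,
           pairs, maxiter: int = 1000) -> np.ndarray:
    def fun(flat):
        X = flat.reshape(-1, 3)
        cache = GeometryCache(params, X, pairs=pairs)
        e = float(energy_total(params, cache)[0])
        g = -forces_batch(params, cache)[0]
        return e, g.ravel()

    res = _scipy_minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter, "ftol": 1e-14,
                                   "gtol": 1e-6})
    return res.x.reshape(-1, 3)


def sample_conformers(ref: ReferenceForceField, mol: Molecule,
                      n_conformers: int, rng: np.random.Generator,
                      thin: int = 15, cart_step: float = 0.012,
                      torsion_step: float = 0.5):
    """Metropolis chain at 500 K from the relaxed geometry.

    Returns (coords (C,N,3), energies, gradients) with oracle-computed
    energies/gradients. The first conformer is the relaxed structure, so
    low-energy coverage is guaranteed; the equilibrated chain supplies the
    high-energy population.
    """
    params = ref.parameters_for(mol)
    pairs = nonbonded_pairs(mol.n_atoms, params.bond_idx, NonbondedSettings())
    x = _relax(params, _embed_coords(mol, rng.integers(1, 2 ** 31 - 1)), pairs)
    kT = BOLTZMANN_KCALMOL * SAMPLER_TEMPERATURE_K
    rot_bonds = _rotatable_bonds(mol)
    sides = {bk: _side_atoms(mol.n_atoms, params.bond_idx, *bk)
             for bk in rot_bonds}

    def mm_energy(X):
        return float(energy_total(params, GeometryCache(params, X, pairs=pairs))[0])

    e_cur = mm_energy(x)
    snapshots = [x.copy()]
    step = 0
    while len(snapshots) < n_conformers:
        step += 1
        prop = x.copy()
        if rot_bonds and step % 3 == 0:
            j, k = rot_bonds[rng.integers(len(rot_bonds))]
            side = sides[(j, k)]
            if side:
                axis = prop[k] - prop[j]
                axis = axis / np.linalg.norm(axis)
                R = Rotation.from_rotvec(axis * rng.normal(0.0, torsion_step))
                prop[side] = R.apply(prop[side] - prop[k]) + prop[k]
        prop += rng.normal(0.0, cart_step, size=prop.shape)
        e_prop = mm_energy(prop)
        if e_prop - e_cur <= 0 or rng.random() < math.exp(-(e_prop - e_cur) / kT):
            x, e_cur = prop, e_prop
        if step % thin == 0:
            snapshots.append(x.copy())

    coords = np.stack(snapshots)
    energies = np.zeros(len(coords))
    grads = np.zeros_like(coords)
    for c, X in enumerate(coords):
        energies[c], grads[c] = oracle_energy(params, X)
    return coords, energies, grads


def build_fixture_set(seed: int, n_conformers: int = 25,
                      smiles=FIXTURE_SMILES,
                      ref: ReferenceForceField | None = None) -> MoleculeDataset:
    """Generate the full synthetic dataset; bit-identical for a given seed.

    Guarantees per molecule: conformer energy spread > 1 kcal/mol and at
    least 10% of conformers >= 3 kcal/mol above that molecule's minimum
    (the chain is extended until both hold).
    """
    ref = ref or ReferenceForceField()
    entries = []
    for idx, smi in enumerate(smiles):
        mol = parse_molecule(smi)
        rng = np.random.default_rng([int(seed) % (2 ** 31), idx])
        coords, energies, grads = sample_conformers(ref, mol, n_conformers, rng)
        extra = 0
        while (energies.max() - energies.min() <= 1.0
               or np.mean(energies >= energies.min() + 3.0) < 0.10):
            extra += 1
            more = sample_conformers(ref, mol, max(4, n_conformers // 4),
                                     np.random.default_rng(
                                         [int(seed) % (2 ** 31), idx, extra]),
                                     cart_step=0.02)
            coords = np.concatenate([coords, more[0]])
            energies = np.concatenate([energies, more[1]])
            grads = np.concatenate([grads, more[2]])
        entries.append(MoleculeEntry(
            molecule=mol, coords=coords, qm_energies=energies,
            qm_gradients=grads, target_charges=ref.target_charges(mol),
            provenance="single-point"))
    return MoleculeDataset(entries)
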