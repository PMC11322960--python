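"""Energies, analytic forces, invariances, and minimization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from graphff.chemgraph import enumerate_terms, featurize, parse_molecule
from graphff.fixtures import oracle_energy
from graphff.mmpotential import (Conformation, GeometryCache, energy,
                                 energy_total, forces, forces_batch, minimize,
                                 nonbonded_pairs, NonbondedSettings)
from graphff.model import MMParameterSet


def bond_only_params(k=100.0, r0=1.5):
    return MMParameterSet(
        n_atoms=2, net_charge=0,
        bond_idx=np.array([[0, 1]]), bond_k=np.array([k]),
        bond_r0=np.array([r0]),
        angle_idx=np.zeros((0, 3), int), angle_k=np.zeros(0),
        angle_theta0=np.zeros(0),
        proper_idx=np.zeros((0, 4), int), proper_k=np.zeros((0, 6)),
        improper_idx=np.zeros((0, 4), int), improper_k=np.zeros((0, 2)),
        q=np.zeros(2), sigma=np.ones(2), epsilon=np.zeros(2))


class TestEnergyConventions:
    def test_half_k_bond_convention(self):
        params = bond_only_params(k=100.0, r0=1.5)
        conf = Conformation(np.array([[0.0, 0, 0], [1.6, 0, 0]]))
        eb = energy(params, conf)
        assert np.isclose(eb.bond, 0.5, atol=1e-12)
        assert np.isclose(eb.total, 0.5, atol=1e-12)

    def test_torsion_n1_at_pi_vanishes(self):
        params = MMParameterSet(
            n_atoms=4, net_charge=0,
            bond_idx=np.array([[0, 1], [1, 2], [2, 3]]),
            bond_k=np.zeros(3), bond_r0=np.ones(3),
            angle_idx=np.zeros((0, 3), int), angle_k=np.zeros(0),
            angle_theta0=np.zeros(0),
            proper_idx=np.array([[0, 1, 2, 3]]),
            proper_k=np.array([[2.0, 0, 0, 0, 0, 0]]),
            improper_idx=np.zeros((0, 4), int), improper_k=np.zeros((0, 2)),
            q=np.zeros(4), sigma=np.ones(4), epsilon=np.zeros(4))
        # planar trans arrangement: phi = pi
        conf = Conformation(np.array([[0.0, 1, 0], [0, 0, 0],
                                      [1, 0, 0], [1, -1, 0]]))
        assert np.isclose(energy(params, conf).proper, 0.0, atol=1e-12)

    def test_breakdown_additivity(self, ref_ff, small_dataset):
        e = small_dataset.entries[0]
        params = ref_ff.parameters_for(e.molecule)
        eb = energy(params, Conformation(e.coords[0]))
        total = eb.bond + eb.angle + eb.proper + eb.improper + eb.lj + eb.coulomb
        assert np.isclose(eb.total, total, atol=1e-10)

    def test_torsion_2pi_periodicity(self, ref_ff, small_dataset):
        e = small_dataset.entries[0]
        params = ref_ff.parameters_for(e.molecule)
        cache = GeometryCache(params, e.coords)
        base = energy_total(params, cache)
        # shifting any dihedral by 2*pi leaves the periodic terms unchanged:
        # use the cosine form directly
        phi = cache.proper_phi
        assert np.allclose(np.cos(3 * (phi + 2 * np.pi)), np.cos(3 * phi))
        assert np.all(phi > -np.pi) and np.all(phi <= np.pi)
        assert np.all(np.isfinite(base))


class TestOracleEquivalence:
    def test_energy_matches_oracle(self, ref_ff, small_dataset):
        for e in small_dataset.entries:
            params = ref_ff.parameters_for(e.molecule)
            for c in range(e.n_conformers):
                mm = energy(params, Conformation(e.coords[c])).total
                oe, _ = oracle_energy(params, e.coords[c])
                assert abs(mm - oe) < 1e-8

    def test_forces_match_oracle_gradient(self, ref_ff, small_dataset):
        for e in small_dataset.entries:
            params = ref_ff.parameters_for(e.molecule)
            f = forces(params, Conformation(e.coords[0]))
            _, grad = oracle_energy(params, e.coords[0])
            assert np.allclose(f, -grad, atol=1e-10)


class TestForces:
    def test_finite_difference_consistency(self, ref_ff, small_dataset, rng):
        h = 1e-4
        e = small_dataset.entries[1]
        params = ref_ff.parameters_for(e.molecule)
        X = e.coords[2]
        f = forces(params, Conformation(X))
        scale = np.abs(f).max()
        for _ in range(12):
            a = rng.integers(X.shape[0])
            c = rng.integers(3)
            Xp, Xm = X.copy(), X.copy()
            Xp[a, c] += h
            Xm[a, c] -= h
            num = -(energy(params, Conformation(Xp)).total
                    - energy(params, Conformation(Xm)).total) / (2 * h)
            assert abs(num - f[a, c]) <= 1e-5 * max(1.0, scale)

    def test_rigid_motion_invariance(self, ref_ff, small_dataset, rng):
        e = small_dataset.entries[2]
        params = ref_ff.parameters_for(e.molecule)
        X = e.coords[0]
        e0 = energy(params, Conformation(X)).total
        R = Rotation.random(random_state=7)
        X2 = R.apply(X) + np.array([3.0, -2.0, 1.0])
        assert abs(energy(params, Conformation(X2)).total - e0) < 1e-8

    def test_translation_leaves_forces_net_zero(self, ref_ff, small_dataset):
        e = small_dataset.entries[0]
        params = ref_ff.parameters_for(e.molecule)
        f1 = forces(params, Conformation(e.coords[0]))
        f2 = forces(params, Conformation(e.coords[0] + 5.0))
        assert np.allclose(f1, f2, atol=1e-9)
        assert np.allclose(f1.sum(axis=0), 0.0, atol=1e-8)

    def test_nonbonded_scaling_categories(self):
        topo = enumerate_terms(featurize(parse_molecule("CCCC")))
        nb = NonbondedSettings()
        pairs, slj, sq = nonbonded_pairs(14, topo.bonds, nb)
        assert set(np.round(np.unique(slj), 4)) <= {round(nb.scale14_lj, 4), 1.0}
        dmap = {tuple(p): (l, q) for p, l, q in zip(pairs.tolist(), slj, sq)}
        # no 1-2 or 1-3 pairs present
        for i, j in topo.bonds:
            assert (min(i, j), max(i, j)) not in dmap


class TestMinimize:
    def test_diatomic_converges_to_r0(self):
        params = bond_only_params(k=300.0, r0=1.5)
        start = Conformation(np.array([[0.0, 0, 0], [1.7, 0, 0]]))
        out = minimize(params, start, tol=1e-6)
        r = np.linalg.norm(out.coords[0] - out.coords[1])
        assert abs(r - 1.5) < 1e-4

    def test_start_at_minimum_stays(self):
        params = bond_only_params(k=300.0, r0=1.5)
        start = Conformation(np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        out = minimize(params, start, tol=1e-6)
        assert np.allclose(out.coords, start.coords, atol=1e-6)

    def test_energy_never_increases(self, ref_ff, small_dataset):
        e = small_dataset.entries[0]
        params = ref_ff.parameters_for(e.molecule)
        start = Conformation(e.coords[3])
        out = minimize(params, start, tol=1e-3)
        assert (energy(params, out).total
                <= energy(params, start).total + 1e-9)
        assert np.abs(forces(params, out)).max() <= 1e-3
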