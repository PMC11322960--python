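"""Symmetry, determinism, and serialization of the parametrization network."""

import numpy as np
import pytest

from graphff.chemgraph import enumerate_terms, featurize, parse_molecule
from graphff.model import (ConfigurationError, ModelWeights, embed_atoms,
                           init_weights, network_forward, parametrize,
                           pool_terms)

WIDTH = 16


@pytest.fixture(scope="module")
def weights():
    return init_weights(width=WIDTH, hidden=WIDTH, seed=3)


class TestEmbeddings:
    def test_methane_hydrogens_equal(self, weights):
        mol = parse_molecule("C")
        emb = embed_atoms(featurize(mol), weights)
        h_idx = [i for i, (s, _) in enumerate(mol.atoms) if s == "H"]
        assert np.allclose(emb[h_idx], emb[h_idx[0]], atol=0, rtol=0)

    def test_width_mismatch_raises(self, weights):
        graph = featurize(parse_molecule("C"))
        bad = ModelWeights(weights.params, dict(weights.hyper, n_features=7))
        with pytest.raises(ConfigurationError):
            embed_atoms(graph, bad)

    def test_disconnected_duplicate_blocks(self, weights):
        single = embed_atoms(featurize(parse_molecule("CCO")), weights)
        double = embed_atoms(featurize(parse_molecule("CCO.CCO")), weights)
        n = single.shape[0]
        assert double.shape[0] == 2 * n
        # the doubled graph is two identical copies: its embedding rows are
        # the single-molecule rows, each appearing twice (any atom order)
        def sorted_rows(x):
            return x[np.lexsort(x.T[::-1])]
        assert np.allclose(sorted_rows(double),
                           sorted_rows(np.vstack([single, single])),
                           atol=1e-12)

    def test_deterministic_for_fixed_seed(self):
        w1 = init_weights(width=8, hidden=8, seed=42)
        w2 = init_weights(width=8, hidden=8, seed=42)
        for k in w1.params:
            assert np.array_equal(w1.params[k], w2.params[k])


@pytest.fixture(scope="module")
def pooled_setup(weights):
    graph = featurize(parse_molecule("CC=O"))
    topo = enumerate_terms(graph)
    emb = embed_atoms(graph, weights)
    return graph, topo, emb


class TestJanossyPooling:
    def test_bond_orientation_invariance(self, pooled_setup, weights):
        graph, topo, emb = pooled_setup
        pooled = pool_terms(emb, topo, weights)
        flipped = topo.bonds[:, ::-1].copy()
        topo2 = type(topo)(bonds=flipped, angles=topo.angles,
                           propers=topo.propers, impropers=topo.impropers)
        pooled2 = pool_terms(emb, topo2, weights)
        assert np.allclose(pooled["bond"], pooled2["bond"], atol=1e-12)

    def test_angle_reversal_invariance(self, pooled_setup, weights):
        graph, topo, emb = pooled_setup
        pooled = pool_terms(emb, topo, weights)
        rev = topo.angles[:, ::-1].copy()
        topo2 = type(topo)(bonds=topo.bonds, angles=rev,
                           propers=topo.propers, impropers=topo.impropers)
        assert np.allclose(pooled["angle"],
                           pool_terms(emb, topo2, weights)["angle"], atol=1e-12)

    def test_proper_reversal_invariance(self, pooled_setup, weights):
        graph, topo, emb = pooled_setup
        pooled = pool_terms(emb, topo, weights)
        rev = topo.propers[:, ::-1].copy()
        topo2 = type(topo)(bonds=topo.bonds, angles=topo.angles,
                           propers=rev, impropers=topo.impropers)
        assert np.allclose(pooled["proper"],
                           pool_terms(emb, topo2, weights)["proper"], atol=1e-12)

    def test_improper_cyclic_relabeling_invariance(self, pooled_setup, weights):
        graph, topo, emb = pooled_setup
        assert len(topo.impropers)
        base = pool_terms(emb, topo, weights)["improper"]
        c, a, b, d = topo.impropers[0]
        for outer in ((b, d, a), (d, a, b)):
            cyc = topo.impropers.copy()
            cyc[0] = (c, *outer)
            topo2 = type(topo)(bonds=topo.bonds, angles=topo.angles,
                               propers=topo.propers, impropers=cyc)
            other = pool_terms(emb, topo2, weights)["improper"]
            assert np.allclose(base[0], other[0], atol=1e-12)


class TestParametrize:
    def test_benzene_bonds_identical_by_symmetry(self, weights, lj_table):
        params = parametrize(parse_molecule("c1ccccc1"), weights, lj_table)
        cc = params.bond_r0[6:]  # C-C ring bonds sort after the 6 C-H bonds
        kinds = {tuple(np.round([k, r], 10))
                 for k, r in zip(params.bond_k, params.bond_r0)}
        assert len(kinds) == 2  # exactly one C-H and one C-C parameter pair

    def test_equivalent_smiles_identical_parameters(self, weights, lj_table):
        p1 = parametrize(parse_molecule("c1ccccc1O"), weights, lj_table)
        p2 = parametrize(parse_molecule("OC1=CC=CC=C1"), weights, lj_table)
        assert p1.to_json() == p2.to_json()

    def test_force_constants_positive_and_ranges(self, weights, lj_table):
        params = parametrize(parse_molecule("CC(=O)[O-]"), weights, lj_table)
        params.validate()

    def test_ethane_equivalent_torsions_share_parameters(self, weights, lj_table):
        params = parametrize(parse_molecule("CC"), weights, lj_table)
        assert len(params.proper_idx) == 9
        assert np.allclose(params.proper_k, params.proper_k[0], atol=1e-10)

    def test_byte_identical_across_runs(self, lj_table):
        mol = parse_molecule("CCN")
        a = parametrize(mol, init_weights(width=8, hidden=8, seed=5), lj_table)
        b = parametrize(mol, init_weights(width=8, hidden=8, seed=5), lj_table)
        assert a.to_json() == b.to_json()

    def test_charges_sum_to_net_charge(self, weights, ref_ff):
        for smi in ("CCO", "[NH4+]", "CC(=O)[O-]"):
            mol = parse_molecule(smi)
            lj = ref_ff.lj_table([mol])
            params = parametrize(mol, weights, lj)
            assert abs(params.q.sum() - params.net_charge) < 1e-10


class TestSerialization:
    def test_checkpoint_roundtrip_bit_exact(self, weights, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        weights.save(path)
        loaded = ModelWeights.load(path)
        assert loaded.hyper == weights.hyper
        for k, v in weights.params.items():
            assert np.array_equal(loaded.params[k], v)

    def test_parameter_json_roundtrip(self, weights, lj_table):
        from graphff.model import MMParameterSet
        params = parametrize(parse_molecule("CC=O"), weights, lj_table)
        back = MMParameterSet.from_json(params.to_json())
        assert back.to_json() == params.to_json()

    def test_zeroed_readout_gives_constant_torsions(self, lj_table):
        w = init_weights(width=8, hidden=8, seed=0)
        for key in list(w.params):
            if key.startswith("read_proper/"):
                w.params[key] = np.zeros_like(w.params[key])
        params = parametrize(parse_molecule("CCC"), w, lj_table)
        assert np.allclose(params.proper_k, 0.0)
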