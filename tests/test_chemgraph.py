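"""Molecule parsing, resonance-insensitive features, and term enumeration."""

import itertools

import numpy as np
import pytest

from graphff.chemgraph import (Molecule, ParseError, UnsupportedChemistryError,
                               enumerate_terms, featurize, parse_molecule)

AROMATIC_PAIRS = [
    ("c1ccccc1", "C1=CC=CC=C1"),
    ("c1ccncc1", "C1=CC=NC=C1"),
    ("c1cc[nH]c1", "C1=CC=CN1"),
    ("c1ccoc1", "C1=CC=CO1"),
    ("c1ccsc1", "C1=CC=CS1"),
    ("Cc1ccccc1", "CC1=CC=CC=C1"),
    ("Oc1ccccc1", "OC1=CC=CC=C1"),
    ("c1ccc2ccccc2c1", "C1=CC=C2C=CC=CC2=C1"),
    ("Cc1ccncc1", "CC1=CC=NC=C1"),
    ("CC(=O)[O-]", "CC([O-])=O"),
]


class TestParsing:
    def test_water_by_valence(self):
        mol = parse_molecule("O")
        assert mol.n_atoms == 3
        assert len(mol.bonds) == 2
        assert mol.net_charge == 0

    def test_ammonium_formal_charge(self):
        mol = parse_molecule("[NH4+]")
        assert mol.n_atoms == 5
        assert mol.net_charge == 1
        assert sum(c for _, c in mol.atoms) == 1

    @pytest.mark.parametrize("a,b", AROMATIC_PAIRS)
    def test_equivalent_sources_same_identity(self, a, b):
        assert parse_molecule(a).identity == parse_molecule(b).identity

    def test_unparsable_source_raises(self):
        with pytest.raises(ParseError):
            parse_molecule("not-a-molecule((")

    def test_radical_rejected(self):
        with pytest.raises(UnsupportedChemistryError):
            parse_molecule("[CH3]")

    def test_sdf_roundtrip_matches_smiles(self, ethanol):
        from rdkit import Chem
        from rdkit.Chem import AllChem
        rdmol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(rdmol, randomSeed=7)
        block = Chem.MolToMolBlock(rdmol)
        mol = parse_molecule(block, add_hydrogens=False)
        assert mol.identity == ethanol.identity
        assert mol.atoms == ethanol.atoms


class TestFeaturize:
    @pytest.mark.parametrize("a,b", AROMATIC_PAIRS)
    def test_resonance_invariance(self, a, b):
        fa = featurize(parse_molecule(a)).node_features
        fb = featurize(parse_molecule(b)).node_features
        assert fa.tobytes() == fb.tobytes()

    def test_methane_hydrogens_identical(self):
        mol = parse_molecule("C")
        g = featurize(mol)
        h_rows = g.node_features[[i for i, (s, _) in enumerate(mol.atoms)
                                  if s == "H"]]
        assert np.all(h_rows == h_rows[0])

    def test_cyclopropane_ring_flags(self):
        mol = parse_molecule("C1CC1")
        g = featurize(mol)
        ring_cols = g.node_features[:, -6:]
        carbons = [i for i, (s, _) in enumerate(mol.atoms) if s == "C"]
        assert np.all(ring_cols[carbons, 0] == 1.0)   # size-3 flag
        assert np.all(ring_cols[carbons, 1:] == 0.0)  # sizes 4..8 unset

    def test_net_charge_graph_level_not_per_atom(self):
        g = featurize(parse_molecule("CC(=O)[O-]"))
        assert g.net_charge == -1
        # both carboxylate oxygens featurized identically (resonance)
        mol = parse_molecule("CC(=O)[O-]")
        oxy = [i for i, (s, _) in enumerate(mol.atoms) if s == "O"]
        f = g.node_features
        assert np.array_equal(f[oxy[0]], f[oxy[1]])

    def test_permuted_sdf_input_gives_permuted_features(self, rng):
        from rdkit import Chem
        from rdkit.Chem import AllChem
        rdmol = Chem.AddHs(Chem.MolFromSmiles("CC(C)O"))
        AllChem.EmbedMolecule(rdmol, randomSeed=3)
        perm = list(rng.permutation(rdmol.GetNumAtoms()))
        shuffled = Chem.RenumberAtoms(rdmol, [int(p) for p in perm])
        f1 = featurize(parse_molecule(Chem.MolToMolBlock(rdmol),
                                      add_hydrogens=False)).node_features
        f2 = featurize(parse_molecule(Chem.MolToMolBlock(shuffled),
                                      add_hydrogens=False)).node_features
        # canonical renumbering makes both orderings identical
        assert f1.tobytes() == f2.tobytes()


def brute_force_terms(graph):
    """Exhaustive enumeration oracle for graphs with <= 12 atoms."""
    adj = set()
    for i, j in graph.adjacency:
        adj.add((int(i), int(j)))
        adj.add((int(j), int(i)))
    n = graph.n_atoms
    bonds = sorted({(i, j) for i, j in adj if i < j})
    angles = sorted({(i, j, k) if i < k else (k, j, i)
                     for i, j, k in itertools.permutations(range(n), 3)
                     if (i, j) in adj and (j, k) in adj and i < k})
    propers = set()
    for i, j, k, l in itertools.permutations(range(n), 4):
        if (i, j) in adj and (j, k) in adj and (k, l) in adj:
            t = (i, j, k, l)
            propers.add(min(t, t[::-1]))
    deg = {a: sum(1 for b in range(n) if (a, b) in adj) for a in range(n)}
    impropers = sorted((c, *sorted(b for b in range(n) if (c, b) in adj))
                       for c in range(n) if deg[c] == 3)
    return bonds, sorted(propers), angles, impropers


class TestEnumerateTerms:
    @pytest.mark.parametrize("smiles,counts", [
        ("O", (2, 1, 0, 0)),
        ("C", (4, 6, 0, 0)),
        ("C=C", (5, 6, 4, 2)),
    ])
    def test_known_counts(self, smiles, counts):
        topo = enumerate_terms(featurize(parse_molecule(smiles)))
        assert topo.counts == counts

    @pytest.mark.parametrize("smiles", [
        "CCO", "C1CC1", "c1ccoc1", "CC(=O)[O-]", "C=CC=C", "CC(C)C",
    ])
    def test_matches_exhaustive_oracle(self, smiles):
        graph = featurize(parse_molecule(smiles))
        topo = enumerate_terms(graph)
        bonds, propers, angles, impropers = brute_force_terms(graph)
        assert [tuple(r) for r in topo.bonds] == bonds
        assert [tuple(r) for r in topo.angles] == angles
        assert [tuple(r) for r in topo.propers] == propers
        assert [tuple(r) for r in topo.impropers] == impropers

    def test_angle_count_formula(self):
        graph = featurize(parse_molecule("CC(C)CC"))
        topo = enumerate_terms(graph)
        nbrs = graph.neighbor_lists()
        expected = sum(len(nb) * (len(nb) - 1) // 2 for nb in nbrs)
        assert len(topo.angles) == expected

    def test_three_ring_degenerate_propers_dropped(self):
        topo = enumerate_terms(featurize(parse_molecule("C1CC1")))
        for i, j, k, l in topo.propers:
            assert i != l
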