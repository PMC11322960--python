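"""Molecules, resonance-insensitive chemical graphs, and valence-term topologies.

The parametrization model never sees bond orders, aromaticity flags, formal
charges, or any other property that changes between resonance forms of the
same molecule. Atoms are described only by element, heavy-atom degree, total
hydrogen count, and ring-size membership (sizes 3-8, perceived by RDKit); the
molecular net charge is carried at graph level for the charge model. This
guarantees that chemically equivalent representations of one molecule (for
example kekulized versus aromatic SMILES of an arene, or the two resonance
forms of a carboxylate) receive byte-identical features and therefore
identical force-field parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "Molecule",
    "ChemicalGraph",
    "TermTopology",
    "ParseError",
    "UnsupportedChemistryError",
    "UnsupportedElementError",
    "parse_molecule",
    "featurize",
    "enumerate_terms",
    "SUPPORTED_ELEMENTS",
]

SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
RING_SIZES = (3, 4, 5, 6, 7, 8)
MAX_HEAVY_DEGREE = 4
MAX_H_COUNT = 4

#: length of the per-atom feature vector
N_FEATURES = len(SUPPORTED_ELEMENTS) + (MAX_HEAVY_DEGREE + 1) + (MAX_H_COUNT + 1) + len(RING_SIZES)


class ParseError(ValueError):
    """The input string could not be interpreted as a molecule."""


class UnsupportedChemistryError(ValueError):
    """Valid molecule, but outside the supported chemistry (e.g. radicals)."""


class UnsupportedElementError(ValueError):
    """An element outside the supported table was encountered."""


@dataclass(frozen=True)
class Molecule:
    """A molecule with explicit hydrogens in canonical atom order.

    ``atoms`` is a list of ``(element symbol, formal charge)``; ``bonds`` a
    list of ``(i, j, integer bond order)`` with ``i < j`` and each pair stored
    once. ``identity`` is the canonical isomeric SMILES and is the key under
    which datasets store per-molecule arrays.
    """

    atoms: tuple
    bonds: tuple
    net_charge: int
    identity: str
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def rdkit_mol(self) -> Chem.Mol:
        """RDKit molecule whose atom numbering matches ``self.atoms``."""
        if self._rdmol is not None:
            return self._rdmol
        return _rdkit_from_source(self.identity, add_hydrogens=True)[0]


@dataclass(frozen=True)
class ChemicalGraph:
    """Featurized molecular graph consumed by the parametrization network."""

    n_atoms: int
    adjacency: np.ndarray        # (n_bonds, 2) int, i < j
    node_features: np.ndarray    # (n_atoms, N_FEATURES) float64
    net_charge: int

    def neighbor_lists(self):
        nbrs = [[] for _ in range(self.n_atoms)]
        for i, j in self.adjacency:
            nbrs[int(i)].append(int(j))
            nbrs[int(j)].append(int(i))
        return [sorted(n) for n in nbrs]


@dataclass(frozen=True)
class TermTopology:
    """Canonical enumeration of valence interaction terms.

    bonds: (B,2) with i<j; angles: (A,3) with j central and i<k; propers:
    (P,4) bonded paths, stored as the lexicographically smaller of the tuple
    and its reversal; impropers: (I,4) as (central, a, b, d) with a<b<d for
    every atom with exactly three bonded neighbors.
    """

    bonds: np.ndarray
    angles: np.ndarray
    propers: np.ndarray
    impropers: np.ndarray

    @property
    def counts(self):
        return (len(self.bonds), len(self.angles), len(self.propers), len(self.impropers))


# ---------------------------------------------------------------------------
# parsing


def _rdkit_from_source(source: str, add_hydrogens: bool):
    """Parse SMILES or an SDF/Mol V2000 block into a sanitized RDKit mol."""
    text = source.strip()
    is_block = "\n" in source or "V2000" in source or "V3000" in source
    if is_block:
        mol = Chem.MolFromMolBlock(source, removeHs=False, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        snippet = text.splitlines()[0][:60] if text else "<empty>"
        raise ParseError(f"could not parse molecule input: {snippet!r}")
    if add_hydrogens or not is_block:
        mol = Chem.AddHs(mol)
    return mol, is_block


def parse_molecule(source: str, add_hydrogens: bool = True) -> Molecule:
    """Parse a SMILES string or SDF(V2000) block into a :class:`Molecule`.

    Atoms are renumbered into RDKit's canonical order so that any two
    equivalent inputs (e.g. kekulized vs aromatic SMILES) yield an identical
    Molecule, atom for atom. Radical species are rejected.
    """
    mol, _ = _rdkit_from_source(source, add_hydrogens)
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            raise UnsupportedChemistryError(
                f"radical species are not supported (atom {atom.GetIdx()}, {atom.GetSymbol()})"
            )
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"element {atom.GetSymbol()!r} is outside the supported table "
                f"{SUPPORTED_ELEMENTS}"
            )
    order = tuple(Chem.CanonicalRankAtoms(mol, breakTies=True))
    # order[i] is the canonical rank of atom i; place atom i at position rank.
    inverse = [0] * mol.GetNumAtoms()
    for i, rank in enumerate(order):
        inverse[rank] = i
    mol = Chem.RenumberAtoms(mol, inverse)
    Chem.SanitizeMol(mol)

    atoms = tuple((a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        order_int = int(round(b.GetBondTypeAsDouble())) or 1
        bonds.append((i, j, order_int))
    bonds = tuple(sorted(bonds))
    net_charge = sum(c for _, c in atoms)
    identity = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)), isomericSmiles=True)
    return Molecule(atoms=atoms, bonds=bonds, net_charge=net_charge,
                    identity=identity, _rdmol=mol)


# ---------------------------------------------------------------------------
# featurization


def featurize(mol: Molecule) -> ChemicalGraph:
    """Build the resonance-insensitive chemical graph for ``mol``.

    Per-atom features: element one-hot over the supported table, heavy-atom
    degree one-hot (0-4), total hydrogen count one-hot (0-4), and membership
    flags for rings of size 3-8. Formal charges and aromaticity are
    deliberately excluded (resonance-sensitive); the molecular net charge is
    stored at graph level.
    """
    rdmol = mol.rdkit_mol()
    ring_info = rdmol.GetRingInfo()
    n = mol.n_atoms
    feats = np.zeros((n, N_FEATURES), dtype=np.float64)
    for i, (symbol, _) in enumerate(mol.atoms):
        if symbol not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"element {symbol!r} is outside the supported table {SUPPORTED_ELEMENTS}"
            )
        atom = rdmol.GetAtomWithIdx(i)
        heavy = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        hcount = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
        col = 0
        feats[i, col + SUPPORTED_ELEMENTS.index(symbol)] = 1.0
        col += len(SUPPORTED_ELEMENTS)
        feats[i, col + min(heavy, MAX_HEAVY_DEGREE)] = 1.0
        col += MAX_HEAVY_DEGREE + 1
        feats[i, col + min(hcount, MAX_H_COUNT)] = 1.0
        col += MAX_H_COUNT + 1
        for k, size in enumerate(RING_SIZES):
            if ring_info.IsAtomInRingOfSize(i, size):
                feats[i, col + k] = 1.0
    adjacency = np.array([[i, j] for i, j, _ in mol.bonds], dtype=np.int64)
    if adjacency.size == 0:
        adjacency = np.zeros((0, 2), dtype=np.int64)
    return ChemicalGraph(n_atoms=n, adjacency=adjacency,
                         node_features=feats, net_charge=mol.net_charge)


# ---------------------------------------------------------------------------
# term enumeration


def enumerate_terms(graph: ChemicalGraph) -> TermTopology:
    """Enumerate bonds, angles, proper and improper torsions canonically.

    Propers degenerate in 3-membered rings (i == l) are dropped; impropers
    exist exactly at atoms with three bonded neighbors, regardless of
    hybridization.
    """
    nbrs = graph.neighbor_lists()
    bonds = sorted((int(i), int(j)) for i, j in graph.adjacency)

    angles = []
    for j in range(graph.n_atoms):
        nb = nbrs[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                if i > k:
                    i, k = k, i
                angles.append((i, j, k))
    angles.sort()

    propers = set()
    for j, k in bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                t = (i, j, k, l)
                propers.add(min(t, t[::-1]))
    propers = sorted(propers)

    impropers = []
    for c in range(graph.n_atoms):
        if len(nbrs[c]) == 3:
            a, b, d = sorted(nbrs[c])
            impropers.append((c, a, b, d))
    impropers.sort()

    def as_array(lst, width):
        if not lst:
            return np.zeros((0, width), dtype=np.int64)
        return np.array(lst, dtype=np.int64)

    return TermTopology(
        bonds=as_array(bonds, 2),
        angles=as_array(angles, 3),
        propers=as_array(propers, 4),
        impropers=as_array(impropers, 4),
    )


def topology_dump(topo: TermTopology) -> dict:
    """JSON-ready dump of the term lists (debug/fixture comparison)."""
    return {
        "bonds": topo.bonds.tolist(),
        "angles": topo.angles.tolist(),
        "propers": topo.propers.tolist(),
        "impropers": topo.impropers.tolist(),
    }
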