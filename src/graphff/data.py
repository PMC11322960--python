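"""Conformer datasets: in-memory containers and the HDF5 archive format.

A dataset is a list of per-molecule entries, each holding the molecule (in
canonical atom order), a batch of conformer coordinates, reference energies
and gradients, target partial charges, and a split label. Archives declare
their units; energies/coordinates are converted to the internal system
(kcal/mol, Å) on load and never re-converted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .chemgraph import Molecule, parse_molecule
from .units import BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL

__all__ = ["ConformerRecord", "MoleculeEntry", "MoleculeDataset"]

PROVENANCE_TAGS = ("single-point", "optimization", "torsion-drive")

_ENERGY_FACTORS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCALMOL}
_LENGTH_FACTORS = {"angstrom": 1.0, "bohr": BOHR_TO_ANGSTROM}


@dataclass(frozen=True)
class ConformerRecord:
    """One geometry with its reference energy and gradient (internal units)."""

    coords: np.ndarray        # (N, 3) Å
    qm_energy: float          # kcal/mol
    qm_gradient: np.ndarray   # (N, 3) kcal/mol/Å  (gradient, not force)
    provenance: str = "single-point"

    def __post_init__(self):
        if self.qm_gradient.shape != self.coords.shape:
            raise ValueError("gradient shape does not match coordinates")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class MoleculeEntry:
    molecule: Molecule
    coords: np.ndarray          # (C, N, 3)
    qm_energies: np.ndarray     # (C,)
    qm_gradients: np.ndarray    # (C, N, 3)
    target_charges: np.ndarray  # (N,)
    provenance: str = "single-point"
    split: str | None = None

    @property
    def n_conformers(self) -> int:
        return len(self.coords)

    def records(self):
        for c in range(self.n_conformers):
            yield ConformerRecord(self.coords[c], float(self.qm_energies[c]),
                                  self.qm_gradients[c], self.provenance)


@dataclass
class MoleculeDataset:
    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def identities(self):
        return [e.molecule.identity for e in self.entries]

    def subset(self, split: str) -> "MoleculeDataset":
        return MoleculeDataset([e for e in self.entries if e.split == split])

    @property
    def n_conformers(self) -> int:
        return sum(e.n_conformers for e in self.entries)

    # -- archive I/O --------------------------------------------------------

    def save(self, path: str):
        with h5py.File(path, "w") as fh:
            fh.attrs["schema"] = "graphff-dataset-1"
            fh.attrs["energy_unit"] = "kcal/mol"
            fh.attrs["length_unit"] = "angstrom"
            for i, e in enumerate(self.entries):
                grp = fh.create_group(f"molecule_{i:05d}")
                grp.attrs["identity"] = e.molecule.identity
                grp.attrs["provenance"] = e.provenance
                grp.attrs["split"] = e.split if e.split is not None else ""
                grp.create_dataset("coords", data=e.coords)
                grp.create_dataset("qm_energies", data=e.qm_energies)
                grp.create_dataset("qm_gradients", data=e.qm_gradients)
                grp.create_dataset("target_charges", data=e.target_charges)

    @classmethod
    def load(cls, path: str) -> "MoleculeDataset":
        entries = []
        with h5py.File(path, "r") as fh:
            fe = _ENERGY_FACTORS[fh.attrs.get("energy_unit", "kcal/mol")]
            fl = _LENGTH_FACTORS[fh.attrs.get("length_unit", "angstrom")]
            fg = fe / fl
            for name in sorted(fh.keys()):
                grp = fh[name]
                mol = parse_molecule(grp.attrs["identity"])
                split = grp.attrs.get("split", "") or None
                entries.append(MoleculeEntry(
                    molecule=mol,
                    coords=np.asarray(grp["coords"]) * fl,
                    qm_energies=np.asarray(grp["qm_energies"]) * fe,
                    qm_gradients=np.asarray(grp["qm_gradients"]) * fg,
                    target_charges=np.asarray(grp["target_charges"]),
                    provenance=grp.attrs.get("provenance", "single-point"),
                    split=split))
        return cls(entries)
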