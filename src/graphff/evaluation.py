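"""Benchmark metrics: centered-energy RMSE, force RMSE, molecule-bootstrap
confidence intervals, and geometry-preservation metrics after minimization.

Energy RMSE follows the standard convention for conformer-energy benchmarks:
both the predicted and reference series are centered to zero mean per
molecule before pooling squared residuals over all conformers, so any
per-molecule additive offset (e.g. heats of formation the MM form cannot
represent) is invisible to the metric. Force RMSE pools all 3N Cartesian
components of all conformers. Confidence intervals resample molecules with
replacement (1000 replicates, 2.5/97.5 percentiles by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .chemgraph import TermTopology
from .mmpotential import Conformation, dihedral_angles
from .training import center_energies

__all__ = ["MetricReport", "energy_rmse", "force_rmse", "bootstrap_ci",
           "geometry_metrics", "evaluate_dataset", "superposed_rmsd"]


@dataclass
class MetricReport:
    energy_rmse: float
    force_rmse: float
    energy_ci: tuple
    force_ci: tuple
    n_molecules: int
    n_conformers: int
    #: pooled-component convention: force RMSE is computed over all 3N
    #: Cartesian components of all conformers of all molecules
    convention: str = "per-molecule centered energies; pooled force components"

    def to_dict(self):
        return {
            "energy_rmse": self.energy_rmse, "force_rmse": self.force_rmse,
            "energy_ci_low": self.energy_ci[0], "energy_ci_high": self.energy_ci[1],
            "force_ci_low": self.force_ci[0], "force_ci_high": self.force_ci[1],
            "n_molecules": self.n_molecules, "n_conformers": self.n_conformers,
            "convention": self.convention,
        }


def energy_rmse(pred, ref, molecule_index) -> float:
    """RMSE over conformers after centering both series per molecule.

    ``molecule_index`` assigns each conformer to a molecule; centering is
    applied within each molecule for both series, so the metric is invariant
    to arbitrary per-molecule offsets in either input.
    """
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    mol = np.asarray(molecule_index)
    if pred.shape != ref.shape or pred.shape != mol.shape:
        raise ValueError("pred, ref and molecule_index must be aligned")
    if pred.size == 0:
        raise ValueError("empty input")
    sq = 0.0
    for m in np.unique(mol):
        mask = mol == m
        resid = center_energies(pred[mask]) - center_energies(ref[mask])
        sq += float(resid @ resid)
    return float(np.sqrt(sq / pred.size))


def force_rmse(pred, ref) -> float:
    """Root mean square over all Cartesian force components."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bootstrap_ci(per_molecule_stats, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95):
    """Percentile bootstrap CI of a pooled RMSE by molecule resampling.

    ``per_molecule_stats`` is a list of ``(sum_of_squares, count)`` pairs,
    one per molecule; the metric for a resample is
    sqrt(sum(ss)/sum(count)) over the drawn molecules.
    """
    stats = [(float(ss), int(n)) for ss, n in per_molecule_stats]
    if len(stats) < 2:
        warnings.warn("bootstrap over a single molecule yields a degenerate CI")
    rng = np.random.default_rng(seed)
    ss = np.array([s for s, _ in stats])
    counts = np.array([n for _, n in stats])
    vals = np.empty(n_boot)
    m = len(stats)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        vals[b] = np.sqrt(ss[idx].sum() / counts[idx].sum())
    alpha = (1.0 - level) / 2.0
    return (float(np.percentile(vals, 100 * alpha)),
            float(np.percentile(vals, 100 * (1 - alpha))))


# ---------------------------------------------------------------------------
# geometry metrics


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Position RMSD after optimal rigid superposition (Kabsch)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("mismatched atom counts")
    if np.array_equal(a, b):
        return 0.0
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    diff = a0 - rot.apply(b0)
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def _wrap_angle(x):
    """Wrap angular differences into (-pi, pi]."""
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def geometry_metrics(mm_min: Conformation, qm_min: Conformation,
                     topo: TermTopology) -> dict:
    """Internal-coordinate and positional agreement of two minimized
    structures of the same molecule.

    Returns position RMSD after superposition and per-structure-pair RMSDs
    of bond lengths (Å), angles, proper and improper dihedrals (reported in
    degrees; angular differences wrapped into (-pi, pi] before squaring).
    """
    xa, xb = mm_min.coords, qm_min.coords
    if xa.shape != xb.shape:
        raise ValueError("mismatched atom counts")
    out = {"position_rmsd": superposed_rmsd(xa, xb)}

    def dist(x, idx):
        return np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)

    def ang(x, idx):
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        c = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1)
                                     * np.linalg.norm(v, axis=1))
        return np.arccos(np.clip(c, -1.0, 1.0))

    out["bond_rmsd"] = (float(np.sqrt(np.mean(
        (dist(xa, topo.bonds) - dist(xb, topo.bonds)) ** 2)))
        if len(topo.bonds) else 0.0)
    out["angle_rmsd_deg"] = (float(np.degrees(np.sqrt(np.mean(
        _wrap_angle(ang(xa, topo.angles) - ang(xb, topo.angles)) ** 2))))
        if len(topo.angles) else 0.0)
    for name, idx in (("proper", topo.propers), ("improper", topo.impropers)):
        if len(idx):
            rows = idx if name == "proper" else idx[:, [1, 0, 2, 3]]
            d = _wrap_angle(dihedral_angles(xa, rows) - dihedral_angles(xb, rows))
            out[f"{name}_rmsd_deg"] = float(np.degrees(np.sqrt(np.mean(d ** 2))))
        else:
            out[f"{name}_rmsd_deg"] = 0.0
    return out


def relative_energy_differences(e_mm, e_qm):
    """ddE per conformer: each method's energies referenced to its own
    minimum-energy conformer of the molecule, then differenced."""
    e_mm = np.asarray(e_mm, dtype=np.float64)
    e_qm = np.asarray(e_qm, dtype=np.float64)
    return (e_mm - e_mm.min()) - (e_qm - e_qm.min())


# ---------------------------------------------------------------------------
# dataset-level evaluation


def evaluate_dataset(weights, entries, lj_table, n_boot: int = 1000,
                     seed: int = 0) -> MetricReport:
    """Energy/force RMSE with bootstrap CIs for a list of dataset entries."""
    from . import model as model_mod
    from .mmpotential import energy_total, forces_batch
    from .training import _assemble_params, _precompute

    if not entries:
        raise ValueError("empty input")
    pre = _precompute(entries, lj_table)
    e_stats, f_stats = [], []
    n_conf = 0
    for pc in pre:
        fwd = model_mod.network_forward(pc.graph, pc.topo, weights)
        params, _, _ = _assemble_params(fwd, pc, pc.entry.molecule)
        resid = center_energies(energy_total(params, pc.cache)) - pc.e_ref_centered
        e_stats.append((float(resid @ resid), resid.size))
        fresid = forces_batch(params, pc.cache) - pc.f_ref
        f_stats.append((float(np.sum(fresid ** 2)), fresid.size))
        n_conf += pc.cache.n_conf
    e_point = float(np.sqrt(sum(s for s, _ in e_stats)
                            / sum(n for _, n in e_stats)))
    f_point = float(np.sqrt(sum(s for s, _ in f_stats)
                            / sum(n for _, n in f_stats)))
    return MetricReport(
        energy_rmse=e_point, force_rmse=f_point,
        energy_ci=bootstrap_ci(e_stats, n_boot, seed),
        force_ci=bootstrap_ci(f_stats, n_boot, seed + 1),
        n_molecules=len(entries), n_conformers=n_conf)
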