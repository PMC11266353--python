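"""Trajectory superposition and per-residue root-mean-square fluctuations.

RMSF quantifies how far a residue's probe atom (Cα by default) wanders from
its time-mean position once global rigid-body motion has been removed by
least-squares superposition.  For pure isotropic Gaussian jitter of σ per
coordinate the expected RMSF is σ√3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "RMSFProfile",
    "align_trajectory",
    "rmsf",
    "write_rmsf_tsv",
]


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) indexed by serial index; NaN where the residue
    lacks the selection atom (those serials are listed in ``missing``)."""

    serial_indices: np.ndarray
    values: np.ndarray
    labels: list[str]
    selection: str
    reference: str
    missing: list[int] = field(default_factory=list)


def _selection_indices(top: Topology, selection: Union[str, Sequence[int]]
                       ) -> np.ndarray:
    """Resolve an alignment selection: 'CA', 'heavy', or explicit indices."""
    if isinstance(selection, str):
        if selection.upper() == "CA":
            idx = [i for i, a in enumerate(top.atoms) if a.name == "CA"]
        elif selection.lower() == "heavy":
            idx = [i for i, a in enumerate(top.atoms) if not a.is_hydrogen]
        else:
            raise ValueError(f"unknown selection {selection!r}; "
                             "use 'CA', 'heavy' or explicit atom indices")
        return np.array(idx, dtype=np.intp)
    return np.asarray(selection, dtype=np.intp)


def _batch_superpose(coords: np.ndarray, sel: np.ndarray,
                     mean_sel: np.ndarray) -> np.ndarray:
    """One alignment pass, vectorised over frames: least-squares proper
    rotation + translation of each frame's selection onto ``mean_sel``,
    applied to all atoms of the frame."""
    mob = coords[:, sel]                       # (F, k, 3)
    cm = mob.mean(axis=1, keepdims=True)       # (F, 1, 3)
    cr = mean_sel.mean(axis=0)
    h = np.einsum("fki,kj->fij", mob - cm, mean_sel - cr) / len(sel)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    d[d == 0] = 1.0
    v = vt.transpose(0, 2, 1).copy()
    v[:, :, 2] *= d[:, None]
    rot = v @ u.transpose(0, 2, 1)             # (F, 3, 3)
    return np.einsum("fij,fkj->fki", rot, coords - cm) + cr


def align_trajectory(traj: Trajectory,
                     selection: Union[str, Sequence[int]] = "CA") -> Trajectory:
    """Superpose every frame onto the mean structure of the selection.

    Iterative fit-to-mean: fit every frame to the current mean of the
    selection, recompute the mean from the fitted frames, and repeat until
    the mean stabilises (coordinate descent on the total squared deviation;
    the slow mode is a decaying global rotation).  Convergence makes the
    operation idempotent to numerical precision.  Boxes are dropped from
    the aligned copy, since superposition breaks periodicity.
    """
    sel = _selection_indices(traj.topology, selection)
    if len(sel) < 3:
        raise ValueError(
            f"alignment selection resolves to {len(sel)} atoms; need ≥ 3")
    coords = traj.coordinates_array()
    prev_mean = None
    for _ in range(500):
        mean_sel = coords[:, sel].mean(axis=0)
        if prev_mean is not None and \
                np.max(np.abs(mean_sel - prev_mean)) < 1e-12:
            break
        coords = _batch_superpose(coords, sel, mean_sel)
        prev_mean = mean_sel
    frames = [Frame(coordinates=coords[k], box=None)
              for k in range(coords.shape[0])]
    return Trajectory(topology=traj.topology, frames=frames)


def rmsf(traj_aligned: Trajectory,
         selection: str = "CA") -> RMSFProfile:
    """Per-residue RMSF of an aligned trajectory.

    ``selection='CA'`` uses each residue's Cα; ``selection='heavy'`` uses
    all non-hydrogen atoms, combining them as the square root of the
    mass-weighted mean of per-atom squared fluctuations.  Displacements are
    measured from each atom's time-mean position.
    """
    top = traj_aligned.topology
    coords = traj_aligned.coordinates_array()
    mean = coords.mean(axis=0)
    sq_fluct = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom, Å²
    masses = top.masses()

    serials = np.array([r.serial_index for r in top.residues])
    values = np.full(top.n_residues, np.nan)
    missing: list[int] = []
    for ri in range(top.n_residues):
        atom_idx = top.atoms_of_residue(ri)
        if selection.upper() == "CA":
            use = [int(i) for i in atom_idx if top.atoms[i].name == "CA"]
        elif selection.lower() == "heavy":
            use = [int(i) for i in atom_idx if not top.atoms[i].is_hydrogen]
        else:
            raise ValueError(f"unknown RMSF selection {selection!r}")
        if not use:
            missing.append(int(serials[ri]))
            continue
        w = masses[use]
        values[ri] = float(np.sqrt(np.average(sq_fluct[use], weights=w)))
    labels = [top.residue_label(i) for i in range(top.n_residues)]
    return RMSFProfile(serial_indices=serials, values=values, labels=labels,
                       selection=selection,
                       reference="time-mean structure after superposition",
                       missing=missing)


def write_rmsf_tsv(profile: RMSFProfile, path: Union[str, Path]) -> None:
    """TSV: serial_index, chain, resnum, resname, rmsf_A."""
    lines = ["serial_index\tchain\tresnum\tresname\trmsf_A"]
    for k, label in enumerate(profile.labels):
        serial, chain, resnum, resname = label.split(":")
        v = profile.values[k]
        val = f"{v:.6f}" if np.isfinite(v) else "NA"
        lines.append(f"{serial}\t{chain}\t{resnum}\t{resname}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")
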