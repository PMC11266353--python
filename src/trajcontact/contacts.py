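"""Residue–residue heavy-atom contact analysis.

A residue pair is *in contact* in a frame when any pair of their
non-hydrogen atoms lies within a cutoff distance (default 4.5 Å,
minimum-image if the frame carries a box).  Averaging the per-frame 0/1
contact indicator over a trajectory gives the contact population map C
(entries in [0, 1]); the difference map ΔC = C_variant − C_reference
localises interactions gained or lost in a modified system.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "ContactMap",
    "DiffContactMap",
    "frame_contacts",
    "contact_population",
    "diff_contact_map",
    "contacts_of_residue",
    "write_contact_map_tsv",
]

DEFAULT_CUTOFF = 4.5  # Å, heavy-atom contact cutoff
DEFAULT_POPULATION_THRESHOLD = 0.5  # "stable contact" = present most of the time


@dataclass
class ContactMap:
    """Symmetric R×R matrix of contact populations in [0, 1] with labels
    ``serial:chain:resnum:resname``; the diagonal is fixed at 0."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact map must be square")
        if not np.allclose(v, v.T):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("contact map diagonal must be zero")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("contact populations must lie in [0, 1]")
        self.values = v

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class DiffContactMap:
    """Difference of two contact maps (variant − reference), entries in [−1, 1]."""

    values: np.ndarray
    labels_variant: list[str]
    labels_reference: list[str]


def frame_contacts(frame: Frame, top: Topology,
                   cutoff: float = DEFAULT_CUTOFF) -> set[tuple[int, int]]:
    """Residue pairs in heavy-atom contact in one frame.

    Returns pairs of 1-based residue serial indices (i, j) with i < j;
    a pair is present iff *any* non-hydrogen atom of one residue is within
    ``cutoff`` (minimum-image if the frame has a box) of any non-hydrogen
    atom of the other.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.flatnonzero(top.heavy_mask())
    coords = frame.coordinates[heavy]
    if frame.box is not None:
        box = np.asarray(frame.box, dtype=float)
        tree = cKDTree(np.mod(coords, box), boxsize=box)
    else:
        tree = cKDTree(coords)
    res_of = np.array([top.atoms[i].residue_index for i in heavy])
    pairs: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(cutoff):
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri != rj:
            si = top.residues[ri].serial_index
            sj = top.residues[rj].serial_index
            pairs.add((min(si, sj), max(si, sj)))
    return pairs


def contact_population(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF,
                       stride: int = 1) -> ContactMap:
    """Trajectory-averaged contact map: entry (i, j) is the fraction of
    (strided) frames in which residues i and j are in contact."""
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    top = traj.topology
    r = top.n_residues
    counts = np.zeros((r, r))
    frames = traj.frames[::stride]
    for frame in frames:
        for si, sj in frame_contacts(frame, top, cutoff):
            counts[si - 1, sj - 1] += 1
    counts += counts.T
    values = counts / len(frames)
    labels = [top.residue_label(i) for i in range(r)]
    return ContactMap(values=values, labels=labels)


def diff_contact_map(c_variant: ContactMap,
                     c_reference: ContactMap) -> DiffContactMap:
    """ΔC = C_variant − C_reference, matched elementwise by serial index.

    The two systems must have the same residue count; a chemically modified
    residue may differ in name (it is matched positionally).
    """
    if c_variant.values.shape != c_reference.values.shape:
        raise ValueError(
            f"contact map dimension mismatch: {c_variant.values.shape} vs "
            f"{c_reference.values.shape}")
    return DiffContactMap(values=c_variant.values - c_reference.values,
                          labels_variant=list(c_variant.labels),
                          labels_reference=list(c_reference.labels))


def contacts_of_residue(cmap: ContactMap, serial_index: int,
                        threshold: float = DEFAULT_POPULATION_THRESHOLD
                        ) -> list[tuple[int, float]]:
    """Partners of one residue with population ≥ threshold, as
    (partner serial index, population), sorted by population descending."""
    r = cmap.n_residues
    if not 1 <= serial_index <= r:
        raise ValueError(f"serial_index {serial_index} outside 1..{r}")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    row = cmap.values[serial_index - 1]
    hits = [(j + 1, float(row[j])) for j in range(r)
            if j + 1 != serial_index and row[j] >= threshold and row[j] > 0]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def write_contact_map_tsv(cmap: Union[ContactMap, DiffContactMap],
                          path: Union[str, Path]) -> None:
    """Write a (difference) contact map as TSV with label header row/column."""
    labels = cmap.labels if isinstance(cmap, ContactMap) else cmap.labels_variant
    lines = ["\t".join(["residue"] + labels)]
    for i, lab in enumerate(labels):
        row = "\t".join(f"{v:.6f}" for v in cmap.values[i])
        lines.append(f"{lab}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")
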