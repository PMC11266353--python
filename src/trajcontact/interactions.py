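"""Geometric detection of hydrogen bonds and aromatic π-π interactions.

Hydrogen bonds use the common geometric convention: an N/O donor with an
attached hydrogen (attachment = H within 1.2 Å of the heavy atom, since PDB
input carries no bond records) and an N/O acceptor, accepted when
H···A ≤ 2.5 Å, D–H···A ≥ 120° and D···A ≤ 3.5 Å.  π-π interactions are
classified from ring center-of-mass separation and the unsigned interplanar
angle θ ∈ [0°, 90°]: *parallel* (θ ≤ 30°), *T-shaped* (θ ≥ 60°, the CH/π
hydrogen-bonding geometry) or *oblique* otherwise, within a 7.0 Å
center-of-mass cutoff.  All thresholds are configurable; the defaults are
documented assumptions, not universal constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (center_of_mass, interplanar_angle,
                       minimum_image_displacement, ring_plane_normal)
from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "PiPiCriteria",
    "PiPiRecord",
    "AromaticRing",
    "InteractionCounts",
    "detect_hbonds",
    "find_aromatic_rings",
    "classify_pipi",
    "count_interactions",
    "RING_TEMPLATES",
]

#: Ring atom-name templates per residue name (each entry: tuple of rings).
RING_TEMPLATES: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "HID": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "HIE": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "HIP": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}

_DONOR_ACCEPTOR_ELEMENTS = ("N", "O")
_H_ATTACH_CUTOFF = 1.2  # Å: hydrogen counted as bonded to its nearest N/O


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond acceptance thresholds."""

    max_ha_distance: float = 2.5   # Å, H···A
    min_dha_angle: float = 120.0   # degrees, D–H···A
    max_da_distance: float = 3.5   # Å, D···A


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor: int       # atom index of donor heavy atom
    hydrogen: int    # atom index of the shared hydrogen
    acceptor: int    # atom index of acceptor heavy atom
    ha_distance: float
    dha_angle: float


@dataclass(frozen=True)
class PiPiCriteria:
    """π-π detection cutoff and angular class boundaries."""

    max_com_distance: float = 7.0  # Å, ring COM–COM
    parallel_max_angle: float = 30.0
    tshaped_min_angle: float = 60.0


@dataclass(frozen=True)
class PiPiRecord:
    frame_index: int
    residue_a: int   # residue serial index
    residue_b: int
    com_distance: float
    interplanar_angle: float
    interaction_class: str  # parallel | T-shaped | oblique


@dataclass
class AromaticRing:
    """An aromatic ring template bound to topology atom indices."""

    residue_serial: int
    atom_names: tuple[str, ...]
    atom_indices: np.ndarray

    def com(self, frame: Frame, masses: np.ndarray) -> np.ndarray:
        return center_of_mass(frame.coordinates[self.atom_indices],
                              masses[self.atom_indices])

    def normal(self, frame: Frame) -> np.ndarray:
        return ring_plane_normal(frame.coordinates[self.atom_indices])


@dataclass
class InteractionCounts:
    """Per-frame hydrogen-bond and π-π counts with trajectory means."""

    hbond_counts: np.ndarray
    pipi_counts: np.ndarray

    @property
    def mean_hbonds(self) -> float:
        return float(np.mean(self.hbond_counts))

    @property
    def mean_pipi(self) -> float:
        return float(np.mean(self.pipi_counts))


def _pair_distance(a: np.ndarray, b: np.ndarray,
                   box: Optional[np.ndarray]) -> float:
    return float(np.linalg.norm(minimum_image_displacement(b - a, box)))


def detect_hbonds(frame: Frame, top: Topology,
                  criteria: HBondCriteria = HBondCriteria(),
                  frame_index: int = 0) -> list[HBondRecord]:
    """All hydrogen bonds in one frame under the geometric criteria.

    Every N/O heavy atom with an attached hydrogen is a candidate donor and
    every N/O heavy atom a candidate acceptor; intra-residue donor–acceptor
    pairs are excluded.

    Raises
    ------
    ValueError
        If the topology contains no hydrogens (H-bond analysis needs a
        model with explicit hydrogens).
    """
    if not top.has_hydrogens():
        raise ValueError(
            "topology contains no hydrogens; hydrogen-bond analysis requires "
            "a structure with explicit hydrogens")
    coords = frame.coordinates
    box = frame.box
    h_idx = [i for i, a in enumerate(top.atoms) if a.is_hydrogen]
    heavy_no = [i for i, a in enumerate(top.atoms)
                if not a.is_hydrogen and a.element in _DONOR_ACCEPTOR_ELEMENTS]
    if not heavy_no:
        return []

    heavy_no_arr = np.array(heavy_no)
    records: list[HBondRecord] = []
    for h in h_idx:
        # donor = nearest N/O within the attachment cutoff
        disp = minimum_image_displacement(coords[heavy_no_arr] - coords[h], box)
        dists = np.linalg.norm(disp, axis=1)
        nearest = int(np.argmin(dists))
        if dists[nearest] > _H_ATTACH_CUTOFF:
            continue
        donor = int(heavy_no_arr[nearest])
        donor_res = top.atoms[donor].residue_index
        for k, acc in enumerate(heavy_no):
            if acc == donor or top.atoms[acc].residue_index == donor_res:
                continue
            ha = dists[k]
            if ha > criteria.max_ha_distance:
                continue
            da = _pair_distance(coords[donor], coords[acc], box)
            if da > criteria.max_da_distance:
                continue
            v_hd = minimum_image_displacement(coords[donor] - coords[h], box)
            v_ha = disp[k]
            cosang = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < criteria.min_dha_angle:
                continue
            records.append(HBondRecord(frame_index=frame_index, donor=donor,
                                       hydrogen=h, acceptor=acc,
                                       ha_distance=float(ha), dha_angle=angle))
    return records


def find_aromatic_rings(top: Topology,
                        extra_templates: Optional[dict[str, Sequence[str]]] = None
                        ) -> list[AromaticRing]:
    """Aromatic rings present in a topology.

    Standard templates cover PHE/TYR (6-ring), TRP (5- and 6-ring) and the
    HIS protonation variants (5-ring).  ``extra_templates`` maps additional
    residue names to ring atom-name tuples — e.g. a lysine–phenylalanine
    conjugate whose ring carries PHE-style atom names.  A residue whose
    template atoms are incomplete is skipped with a warning, not an error.
    """
    templates = {k: tuple(tuple(r) for r in v) for k, v in RING_TEMPLATES.items()}
    if extra_templates:
        for resname, ring in extra_templates.items():
            if ring and isinstance(ring[0], (list, tuple)):
                templates[resname] = tuple(tuple(r) for r in ring)
            else:
                templates[resname] = (tuple(ring),)
    rings: list[AromaticRing] = []
    for ri, res in enumerate(top.residues):
        for ring_names in templates.get(res.name, ()):
            if not 5 <= len(ring_names) <= 6:
                raise ValueError(f"ring template for {res.name} must have 5 or 6 atoms")
            by_name = {top.atoms[i].name: int(i) for i in top.atoms_of_residue(ri)}
            try:
                idx = np.array([by_name[n] for n in ring_names], dtype=np.intp)
            except KeyError as missing:
                warnings.warn(
                    f"residue {res.chain_id}{res.author_number} ({res.name}): "
                    f"ring atom {missing} missing, ring skipped")
                continue
            rings.append(AromaticRing(residue_serial=res.serial_index,
                                      atom_names=tuple(ring_names),
                                      atom_indices=idx))
    return rings


def classify_pipi(ring_a: AromaticRing, ring_b: AromaticRing, frame: Frame,
                  top: Topology, criteria: PiPiCriteria = PiPiCriteria(),
                  frame_index: int = 0) -> Optional[PiPiRecord]:
    """Classify one ring pair in one frame, or return None beyond the cutoff.

    Symmetric in its ring arguments; the interplanar angle is folded to
    [0°, 90°] since plane normals have arbitrary sign.
    """
    if ring_a.residue_serial == ring_b.residue_serial:
        raise ValueError("π-π classification requires rings from distinct residues")
    masses = top.masses()
    com_a = ring_a.com(frame, masses)
    com_b = ring_b.com(frame, masses)
    dist = _pair_distance(com_a, com_b, frame.box)
    if dist > criteria.max_com_distance:
        return None
    theta = interplanar_angle(ring_a.normal(frame), ring_b.normal(frame))
    if theta <= criteria.parallel_max_angle:
        cls = "parallel"
    elif theta >= criteria.tshaped_min_angle:
        cls = "T-shaped"
    else:
        cls = "oblique"
    sa, sb = sorted((ring_a.residue_serial, ring_b.residue_serial))
    return PiPiRecord(frame_index=frame_index, residue_a=sa, residue_b=sb,
                      com_distance=dist, interplanar_angle=theta,
                      interaction_class=cls)


def count_interactions(traj: Trajectory,
                       hbond_criteria: HBondCriteria = HBondCriteria(),
                       pipi_criteria: PiPiCriteria = PiPiCriteria(),
                       extra_ring_templates: Optional[dict[str, Sequence[str]]] = None,
                       stride: int = 1) -> InteractionCounts:
    """Per-frame totals of hydrogen bonds and π-π interactions.

    π-π counting considers every ring pair from distinct residues; a pair
    contributes one count per frame when within the COM cutoff, whatever its
    angular class (the per-record class remains available via
    :func:`classify_pipi`).
    """
    rings = find_aromatic_rings(traj.topology, extra_ring_templates)
    frames = traj.frames[::stride]
    hb = np.zeros(len(frames), dtype=int)
    pp = np.zeros(len(frames), dtype=int)
    for k, frame in enumerate(frames):
        hb[k] = len(detect_hbonds(frame, traj.topology, hbond_criteria, k))
        n_pp = 0
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if rings[i].residue_serial == rings[j].residue_serial:
                    continue
                rec = classify_pipi(rings[i], rings[j], frame, traj.topology,
                                    pipi_criteria, k)
                if rec is not None:
                    n_pp += 1
        pp[k] = n_pp
    return InteractionCounts(hbond_counts=hb, pipi_counts=pp)
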