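"""Core in-memory containers for protein conformational ensembles.

A :class:`Trajectory` is a :class:`Topology` (atoms grouped into residues,
built from the first model of a multi-model PDB) plus an ordered list of
coordinate :class:`Frame` objects in Å.  Residues carry a 1-based
*serial index* assigned in chain-concatenated file order — for an insulin
monomer (21-residue A chain followed by the 30-residue B chain) A1 maps to
serial 1, A21 to 21, B1 to 22 and B30 to 51.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Frame",
    "Trajectory",
    "NonbondedParams",
    "TopologyError",
    "residue_serial_map",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (u) for the elements that occur in protein PDB files.
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
}


class TopologyError(ValueError):
    """Raised for inconsistent topologies or residue-numbering clashes."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``name`` follows PDB columns 13–16 semantics (stripped);
    ``residue_index`` is a 0-based index into ``Topology.residues``.
    """

    serial: int
    name: str
    element: str
    residue_index: int

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


@dataclass(frozen=True)
class Residue:
    """A residue with its author (PDB) numbering and chain-concatenated serial.

    ``serial_index`` is 1-based and strictly increasing in file order.
    """

    name: str
    chain_id: str
    author_number: int
    serial_index: int


class Topology:
    """Ordered atoms partitioned into ordered residues."""

    def __init__(self, atoms: Sequence[Atom], residues: Sequence[Residue]):
        self.atoms: list[Atom] = list(atoms)
        self.residues: list[Residue] = list(residues)
        self._validate()
        # residue -> atom indices (contiguity is validated above)
        self._res_atoms: list[np.ndarray] = [
            np.array([i for i, a in enumerate(self.atoms) if a.residue_index == r],
                     dtype=np.intp)
            for r in range(len(self.residues))
        ]

    def _validate(self) -> None:
        if not self.atoms:
            raise TopologyError("topology has no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("duplicate atom serial numbers in topology")
        n_res = len(self.residues)
        last = -1
        for a in self.atoms:
            if not (0 <= a.residue_index < n_res):
                raise TopologyError(f"atom {a.serial} references missing residue")
            if a.residue_index < last:
                raise TopologyError(
                    f"atoms of residue {a.residue_index} are not contiguous")
            last = a.residue_index
        for k, res in enumerate(self.residues):
            if res.serial_index != k + 1:
                raise TopologyError(
                    f"residue serial_index {res.serial_index} out of order "
                    f"(expected {k + 1})")

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def atoms_of_residue(self, residue_index: int) -> np.ndarray:
        """0-based atom indices of one residue (by 0-based residue index)."""
        return self._res_atoms[residue_index]

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def element_array(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def atom_index(self, chain_id: str, author_number: int, name: str) -> int:
        """Index of the unique atom matching (chain, resnum, name)."""
        hits = self.find_atoms(chain_id, author_number, name)
        if len(hits) != 1:
            raise TopologyError(
                f"selection {chain_id}:{author_number}:{name} matched "
                f"{len(hits)} atoms: {hits}")
        return hits[0]

    def find_atoms(self, chain_id: str, author_number: int, name: str) -> list[int]:
        out = []
        for ri, res in enumerate(self.residues):
            if res.chain_id == chain_id and res.author_number == author_number:
                for ai in self._res_atoms[ri]:
                    if self.atoms[ai].name == name:
                        out.append(int(ai))
        return out

    def residue_by_author(self, chain_id: str, author_number: int) -> int:
        """0-based residue index for (chain, author number)."""
        for ri, res in enumerate(self.residues):
            if res.chain_id == chain_id and res.author_number == author_number:
                return ri
        raise TopologyError(f"no residue {chain_id}{author_number} in topology")

    def residue_label(self, residue_index: int) -> str:
        r = self.residues[residue_index]
        return f"{r.serial_index}:{r.chain_id}:{r.author_number}:{r.name}"

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)


@dataclass
class Frame:
    """One set of coordinates (N×3, Å) with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N×3 array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths (Å)")


@dataclass
class Trajectory:
    """A topology with one or more coordinate frames of identical atom count."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, "
                    f"topology has {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coordinates_array(self) -> np.ndarray:
        """All coordinates stacked to (n_frames, n_atoms, 3)."""
        return np.stack([fr.coordinates for fr in self.frames])


def residue_serial_map(top: Topology) -> dict[tuple[str, int], int]:
    """Map (chain_id, author_number) → 1-based chain-concatenated serial index.

    Serial indices follow occurrence order in the file, so author-numbering
    gaps do not create serial gaps.  For insulin (A chain of 21 residues then
    B chain of 30) this yields A1→1, A21→21, B1→22, B30→51.

    Raises
    ------
    TopologyError
        If two residues share the same (chain, author number).
    """
    out: dict[tuple[str, int], int] = {}
    for res in top.residues:
        key = (res.chain_id, res.author_number)
        if key in out:
            raise TopologyError(
                f"duplicate residue number {res.chain_id}{res.author_number}")
        out[key] = res.serial_index
    return out


@dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters: charge q (e), LJ sigma (Å), epsilon
    (kcal/mol), plus an exclusion list of atom-index pairs that do not
    interact (bonded neighbours)."""

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    exclusions: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        n = len(self.charge)
        if len(self.sigma) != n or len(self.epsilon) != n:
            raise ValueError("charge, sigma, epsilon must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")
        self.exclusions = {tuple(sorted(p)) for p in self.exclusions}
        for i, j in self.exclusions:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"exclusion pair ({i},{j}) references missing atom")
        self._pair_cache: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def interacting_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j), i<j, of all non-excluded atom pairs."""
        if self._pair_cache is None:
            n = self.n_atoms
            iu, ju = np.triu_indices(n, k=1)
            if self.exclusions:
                excl = np.zeros((n, n), dtype=bool)
                for a, b in self.exclusions:
                    excl[a, b] = True
                keep = ~excl[iu, ju]
                iu, ju = iu[keep], ju[keep]
            self._pair_cache = (iu, ju)
        return self._pair_cache
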