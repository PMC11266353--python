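"""Multi-model PDB reading/writing and nonbonded-parameter tables.

The first MODEL defines the topology; every further MODEL must present the
same atoms in the same order and becomes one coordinate frame.  Only
orthorhombic CRYST1 boxes are honoured (all angles 90°); anything else is
treated as "no box".  Waters and monatomic ions are stripped by default
(``keep_solvent=True`` retains them); HETATM records on protein chains —
e.g. a chemically modified residue — are always retained.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .trajectory import (Atom, Frame, NonbondedParams, Residue, Topology,
                         Trajectory)

__all__ = [
    "PDBParseError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_params_table",
    "default_exclusions",
]

logger = logging.getLogger(__name__)

#: Residue names treated as solvent/ions and dropped unless keep_solvent.
SOLVENT_RESNAMES = frozenset({
    "HOH", "WAT", "TIP", "TIP3", "TP3", "SOL", "SPC",
    "NA", "NA+", "CL", "CL-", "K", "K+", "MG", "ZN", "CS", "BR", "IOD", "LI",
})

class PDBParseError(ValueError):
    """Raised for malformed multi-model PDB input, with file context."""


def _element_from_name(name: str) -> str:
    """Leading-character heuristic used when the element column is blank.

    Digits are skipped ('1HB' → H); a leading H/D means hydrogen/deuterium;
    otherwise the first alphabetic character is the element symbol.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: unparseable coordinate field ({exc})") from None
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = -1  # overflow markers like ***** are tolerated; reassigned later
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: unparseable residue number ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    return {
        "serial": serial,
        "name": line[12:16].strip(),
        "resname": line[17:20].strip(),
        "chain": line[21].strip() or " ",
        "resnum": resnum,
        "xyz": (x, y, z),
        "element": element,
    }


def read_multimodel_pdb(path: Union[str, Path],
                        keep_solvent: bool = False) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Parameters
    ----------
    path : str or Path
        PDB file with one or more MODEL/ENDMDL blocks (a file with no MODEL
        records is treated as a single implicit model).
    keep_solvent : bool
        Retain water/ion residues (dropped by default).

    Raises
    ------
    PDBParseError
        On atom-count mismatch between models (naming the model) or on an
        unparseable field (naming the line number).
    """
    path = Path(path)
    box: Optional[np.ndarray] = None
    models: list[list[dict]] = []
    model_numbers: list[int] = []
    current: Optional[list[dict]] = None
    saw_model_record = False

    with open(path) as fh:  # text mode: line endings (LF/CRLF) normalised
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    alpha, beta, gamma = (float(line[33:40]), float(line[40:47]),
                                          float(line[47:54]))
                except ValueError as exc:
                    raise PDBParseError(
                        f"line {lineno}: unparseable CRYST1 record ({exc})") from None
                if all(abs(ang - 90.0) < 1e-3 for ang in (alpha, beta, gamma)) \
                        and min(a, b, c) > 1.0:
                    box = np.array([a, b, c])
                else:
                    logger.info("%s: non-orthorhombic or placeholder CRYST1; "
                                "box treated as absent", path.name)
            elif rec.startswith("MODEL"):
                saw_model_record = True
                try:
                    model_numbers.append(int(line[6:].split()[0]))
                except (ValueError, IndexError):
                    model_numbers.append(len(models) + 1)
                current = []
                models.append(current)
            elif rec.startswith("ENDMDL"):
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if not keep_solvent and atom["resname"] in SOLVENT_RESNAMES:
                    continue
                if current is None:
                    if saw_model_record and models:
                        # stray atom outside MODEL blocks after the first
                        raise PDBParseError(
                            f"line {lineno}: ATOM record outside MODEL block")
                    current = []
                    models.append(current)
                    model_numbers.append(1)
                current.append(atom)

    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    topology = _build_topology(models[0], path.name)
    n = topology.n_atoms
    frames: list[Frame] = []
    for k, model in enumerate(models):
        if len(model) != n:
            raise PDBParseError(
                f"{path}: model {model_numbers[k]} has {len(model)} atoms, "
                f"expected {n} (model 1)")
        coords = np.array([a["xyz"] for a in model], dtype=float)
        frames.append(Frame(coordinates=coords, box=box))
    return Trajectory(topology=topology, frames=frames)


def _build_topology(records: list[dict], filename: str) -> Topology:
    atoms: list[Atom] = []
    residues: list[Residue] = []
    res_key = None
    used_heuristic = False
    for rec in records:
        key = (rec["chain"], rec["resnum"], rec["resname"])
        if key != res_key:
            residues.append(Residue(name=rec["resname"], chain_id=rec["chain"],
                                    author_number=rec["resnum"],
                                    serial_index=len(residues) + 1))
            res_key = key
        element = rec["element"]
        if not element:
            element = _element_from_name(rec["name"])
            used_heuristic = True
        else:
            element = element[:2].upper()
        serial = rec["serial"] if rec["serial"] >= 0 else len(atoms) + 1
        atoms.append(Atom(serial=serial, name=rec["name"], element=element,
                          residue_index=len(residues) - 1))
    # serial uniqueness can be violated by overflow markers; renumber then
    if len({a.serial for a in atoms}) != len(atoms):
        atoms = [Atom(serial=i + 1, name=a.name, element=a.element,
                      residue_index=a.residue_index) for i, a in enumerate(atoms)]
    if used_heuristic:
        logger.info("%s: element column absent for some atoms; "
                    "used leading-character heuristic on atom names", filename)
    return Topology(atoms=atoms, residues=residues)


def write_multimodel_pdb(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a standard fixed-column multi-model PDB."""
    path = Path(path)
    top = traj.topology
    coords_ok = all(np.all(np.abs(fr.coordinates) < 10000.0) for fr in traj.frames)
    if not coords_ok:
        raise ValueError("coordinates exceed the PDB %8.3f field width (|x| ≥ 10000 Å)")
    lines: list[str] = []
    box = traj.frames[0].box
    if box is not None:
        lines.append(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1")
    for m, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, atom in enumerate(top.atoms):
            res = top.residues[atom.residue_index]
            lines.append(_atom_line(atom, res, frame.coordinates[i]))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _atom_line(atom: Atom, res: Residue, xyz: np.ndarray) -> str:
    name = atom.name
    # standard PDB alignment: 1–3 character names start in column 14 unless
    # they begin with a digit; 4-character names fill columns 13–16
    if len(name) < 4 and not name[:1].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    element = atom.element.rjust(2)[:2]
    return (f"ATOM  {atom.serial % 100000:5d} {name_field} {res.name:>3s} "
            f"{res.chain_id}{res.author_number:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element}")


def read_params_table(path: Union[str, Path], top: Topology) -> NonbondedParams:
    """Read a TSV nonbonded-parameter table and map it onto a topology.

    Expected header: ``chain  resnum  atom_name  q  sigma  epsilon``.
    ``*`` acts as a wildcard in the chain and resnum columns (a wildcard row
    parameterises every atom of that name); exact rows take precedence.

    Raises
    ------
    ValueError
        Listing every atom left without parameters, or naming the row with a
        non-numeric field.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["chain", "resnum", "atom_name", "q", "sigma", "epsilon"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: parameter table missing columns {missing_cols}")
    for col in ("q", "sigma", "epsilon"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at data row "
                f"{int(bad[0]) + 2} (counting the header as row 1)")
        df[col] = vals

    exact: dict[tuple[str, str, str], tuple[float, float, float]] = {}
    wild: dict[str, tuple[float, float, float]] = {}
    half: dict[tuple[str, str], tuple[float, float, float]] = {}
    for _, row in df.iterrows():
        key_vals = (float(row["q"]), float(row["sigma"]), float(row["epsilon"]))
        chain, resnum, name = str(row["chain"]), str(row["resnum"]), str(row["atom_name"])
        if chain == "*" and resnum == "*":
            wild[name] = key_vals
        elif chain == "*" or resnum == "*":
            half[(chain, resnum, name) if False else (f"{chain}|{resnum}", name)] = key_vals
        else:
            exact[(chain, resnum, name)] = key_vals

    n = top.n_atoms
    q = np.zeros(n)
    sigma = np.zeros(n)
    eps = np.zeros(n)
    unmatched: list[str] = []
    for i, atom in enumerate(top.atoms):
        res = top.residues[atom.residue_index]
        keys = [
            exact.get((res.chain_id, str(res.author_number), atom.name)),
            half.get((f"{res.chain_id}|*", atom.name)),
            half.get((f"*|{res.author_number}", atom.name)),
            wild.get(atom.name),
        ]
        hit = next((k for k in keys if k is not None), None)
        if hit is None:
            unmatched.append(f"{res.chain_id}{res.author_number}:{atom.name}")
        else:
            q[i], sigma[i], eps[i] = hit
    if unmatched:
        raise ValueError(
            f"{path}: no parameters for {len(unmatched)} atom(s): "
            + ", ".join(unmatched[:20]))
    return NonbondedParams(charge=q, sigma=sigma, epsilon=eps,
                           exclusions=default_exclusions(top))


#: Backbone atom names involved in the peptide-bond bridge between
#: sequence-adjacent residues.
_PEPTIDE_BRIDGE = frozenset({"C", "O", "N", "H", "CA"})


def default_exclusions(top: Topology) -> set[tuple[int, int]]:
    """Nonbonded exclusion list used when no bond table is available:
    all intra-residue pairs, plus peptide-bond-bridging backbone pairs
    (C, O, N, H, CA) of residues adjacent in the same chain.  This removes
    the absurd bonded Coulomb terms without requiring full bond topology.
    """
    excl: set[tuple[int, int]] = set()
    for ri in range(top.n_residues):
        idx = top.atoms_of_residue(ri)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                excl.add((int(idx[a]), int(idx[b])))
    for ri in range(top.n_residues - 1):
        r1, r2 = top.residues[ri], top.residues[ri + 1]
        if r1.chain_id != r2.chain_id:
            continue
        idx1 = [int(i) for i in top.atoms_of_residue(ri)
                if top.atoms[i].name in _PEPTIDE_BRIDGE]
        idx2 = [int(i) for i in top.atoms_of_residue(ri + 1)
                if top.atoms[i].name in _PEPTIDE_BRIDGE]
        for a in idx1:
            for b in idx2:
                excl.add(tuple(sorted((a, b))))
    return excl
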