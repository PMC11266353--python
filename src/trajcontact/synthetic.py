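"""Seeded toy-trajectory generator with known ground truth.

This module stands in for microsecond-scale MD data: it builds small
two-chain peptide ensembles in which every analysed feature is *designed* —
residue pairs in heavy-atom contact in a prescribed fraction of frames,
a backbone C=O···H–N hydrogen bond with a unimodal distance distribution,
an aromatic ring pair with prescribed center-of-mass separation and
interplanar angle, and per-residue isotropic Gaussian positional jitter —
so each analysis module can be checked against closed-form expectations.

Toy residues carry a minimal atom set (N, H, CA, C, O, plus an ideal
six-membered ring where directed); realism of the dynamics is explicitly
not a goal, exactness of the ground truth is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .trajectory import (Atom, Frame, NonbondedParams, Residue, Topology,
                         Trajectory)
from .pdb_io import default_exclusions

__all__ = [
    "ChainSpec",
    "ContactDirective",
    "HBondDirective",
    "RingPairDirective",
    "FixtureSpec",
    "FixtureResult",
    "generate_fixture",
    "insulin_like_pair",
    "default_toy_params",
    "write_manifest_tsv",
    "INSULIN_A_SEQUENCE",
    "INSULIN_B_SEQUENCE",
]

# minimal residue template: local coordinates (Å) relative to the residue
# origin (its backbone N); the N–H bond points along -y so that directive
# geometry has a fixed reference direction
_BACKBONE_TEMPLATE = (
    ("N", "N", np.array([0.0, 0.0, 0.0])),
    ("H", "H", np.array([0.0, -1.01, 0.0])),
    ("CA", "C", np.array([1.2, 0.6, 0.0])),
    ("C", "C", np.array([2.4, 0.0, 0.0])),
    ("O", "O", np.array([2.6, -1.2, 0.0])),
)
_NH_DIRECTION = np.array([0.0, -1.0, 0.0])  # unit vector N→H in the template

#: PHE/TYR-style six-ring atom names with their hexagon angles (degrees)
_RING_ATOMS = (("CG", 90.0), ("CD1", 150.0), ("CD2", 30.0),
               ("CE1", 210.0), ("CE2", -30.0), ("CZ", 270.0))
_RING_RADIUS = 1.39  # Å, aromatic C–C ring circumradius
_RING_OFFSET = np.array([1.2, 3.1, 0.0])  # ring center relative to residue origin

INSULIN_A_SEQUENCE = ("GLY ILE VAL GLU GLN CYS CYS THR SER ILE CYS SER LEU "
                      "TYR GLN LEU GLU ASN TYR CYS ASN").split()
INSULIN_B_SEQUENCE = ("PHE VAL ASN GLN HIS LEU CYS GLY SER HIS LEU VAL GLU "
                      "ALA LEU TYR LEU VAL CYS GLY GLU ARG GLY PHE PHE TYR "
                      "THR PRO LYS THR").split()

ResidueKey = tuple[str, int]  # (chain_id, author_number)


@dataclass
class ChainSpec:
    chain_id: str
    residue_names: list[str]


@dataclass
class ContactDirective:
    """Keep residue ``mobile`` in heavy-atom contact with residue ``anchor``
    in a prescribed fraction of frames (schedule drawn once by seeded
    shuffle, with exactly round(population·frames) contact frames)."""

    anchor: ResidueKey
    mobile: ResidueKey
    population: float
    contact_distance: float = 4.0  # Å, CA–CA in contact frames
    apart_distance: float = 8.0    # Å, CA–CA otherwise


@dataclass
class HBondDirective:
    """Maintain a backbone N–H···O=C hydrogen bond between a donor and an
    acceptor residue with Gaussian-jittered H···O distance and near-linear
    D–H···A angle."""

    donor: ResidueKey
    acceptor: ResidueKey
    mean_distance: float = 2.0   # Å, H···O
    distance_sigma: float = 0.15
    angle_sigma_deg: float = 10.0  # deviation from linearity
    mobile: str = "acceptor"     # which residue is repositioned


@dataclass
class RingPairDirective:
    """Hold two aromatic rings at a prescribed center-of-mass separation and
    interplanar angle (T-shaped near 90°), with Gaussian jitter on both."""

    anchor: ResidueKey
    mobile: ResidueKey
    mean_com_distance: float = 5.0  # Å
    com_sigma: float = 0.3
    mean_angle_deg: float = 90.0
    angle_sigma_deg: float = 5.0


@dataclass
class FixtureSpec:
    """Full description of a synthetic ensemble; deterministic per seed."""

    chains: list[ChainSpec]
    n_frames: int = 100
    seed: int = 0
    contacts: list[ContactDirective] = field(default_factory=list)
    hbonds: list[HBondDirective] = field(default_factory=list)
    ring_pairs: list[RingPairDirective] = field(default_factory=list)
    ring_residues: list[ResidueKey] = field(default_factory=list)
    sigma: dict[ResidueKey, float] = field(default_factory=dict)
    default_sigma: float = 0.0
    box: Optional[tuple[float, float, float]] = None
    rigid_body_motion: bool = False
    residue_spacing: float = 9.0   # Å between residue origins along a chain
    chain_spacing: float = 40.0    # Å between chains

    def validate(self) -> None:
        keys = {(c.chain_id, i + 1) for c in self.chains
                for i in range(len(c.residue_names))}
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        mobile_seen: set[ResidueKey] = set()

        def check(key: ResidueKey, what: str) -> None:
            if key not in keys:
                raise ValueError(f"{what} residue {key} not in chain plan")

        for d in self.contacts:
            check(d.anchor, "contact anchor")
            check(d.mobile, "contact mobile")
            if not 0.0 <= d.population <= 1.0:
                raise ValueError("contact population must lie in [0, 1]")
            if d.mobile in mobile_seen:
                raise ValueError(
                    f"contradictory directives: residue {d.mobile} is mobile "
                    "in more than one directive")
            mobile_seen.add(d.mobile)
        for rp in self.ring_pairs:
            check(rp.anchor, "ring anchor")
            check(rp.mobile, "ring mobile")
            if rp.mobile in mobile_seen:
                raise ValueError(
                    f"contradictory directives: residue {rp.mobile} is mobile "
                    "in more than one directive")
            mobile_seen.add(rp.mobile)
        for hb in self.hbonds:
            check(hb.donor, "hbond donor")
            check(hb.acceptor, "hbond acceptor")
            if hb.mobile not in ("donor", "acceptor"):
                raise ValueError("hbond mobile must be 'donor' or 'acceptor'")
            mob = hb.donor if hb.mobile == "donor" else hb.acceptor
            if mob in mobile_seen:
                raise ValueError(
                    f"contradictory directives: residue {mob} is mobile "
                    "in more than one directive")
            mobile_seen.add(mob)
        for key, s in self.sigma.items():
            check(key, "sigma")
            if s < 0:
                raise ValueError("fluctuation sigma must be ≥ 0")
        for key in self.ring_residues:
            check(key, "ring")

    def mobile_keys(self) -> set[ResidueKey]:
        out = {d.mobile for d in self.contacts}
        out |= {rp.mobile for rp in self.ring_pairs}
        out |= {hb.donor if hb.mobile == "donor" else hb.acceptor
                for hb in self.hbonds}
        return out


@dataclass
class FixtureResult:
    trajectory: Trajectory
    params: NonbondedParams
    manifest: dict


def _build_topology(spec: FixtureSpec) -> tuple[Topology, dict[ResidueKey, int]]:
    """Topology plus (chain, resnum) → 0-based residue index."""
    ring_set = set(spec.ring_residues)
    for rp in spec.ring_pairs:
        ring_set.add(rp.anchor)
        ring_set.add(rp.mobile)
    atoms: list[Atom] = []
    residues: list[Residue] = []
    index: dict[ResidueKey, int] = {}
    serial = 0
    for chain in spec.chains:
        for i, resname in enumerate(chain.residue_names):
            key = (chain.chain_id, i + 1)
            residues.append(Residue(name=resname, chain_id=chain.chain_id,
                                    author_number=i + 1,
                                    serial_index=len(residues) + 1))
            index[key] = len(residues) - 1
            names = [(n, el) for n, el, _ in _BACKBONE_TEMPLATE]
            if key in ring_set:
                names += [(n, "C") for n, _ in _RING_ATOMS]
            for name, el in names:
                serial += 1
                atoms.append(Atom(serial=serial, name=name, element=el,
                                  residue_index=len(residues) - 1))
    return Topology(atoms=atoms, residues=residues), index


def _base_coordinates(spec: FixtureSpec, top: Topology,
                      index: dict[ResidueKey, int]) -> np.ndarray:
    coords = np.zeros((top.n_atoms, 3))
    for ci, chain in enumerate(spec.chains):
        for i in range(len(chain.residue_names)):
            key = (chain.chain_id, i + 1)
            ri = index[key]
            origin = np.array([i * spec.residue_spacing,
                               ci * spec.chain_spacing, 0.0])
            atom_idx = top.atoms_of_residue(ri)
            local = {n: xyz for n, _, xyz in _BACKBONE_TEMPLATE}
            ring_center = origin + _RING_OFFSET
            for ai in atom_idx:
                name = top.atoms[ai].name
                if name in local:
                    coords[ai] = origin + local[name]
                else:  # ring atom: ideal hexagon in the xy-plane
                    ang = np.radians(dict(_RING_ATOMS)[name])
                    coords[ai] = ring_center + _RING_RADIUS * np.array(
                        [np.cos(ang), np.sin(ang), 0.0])
    return coords


def _rotate_about_axis(v: np.ndarray, axis: np.ndarray, angle_rad: float
                       ) -> np.ndarray:
    """Rodrigues rotation of vector v about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle_rad)
            + np.cross(axis, v) * np.sin(angle_rad)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle_rad)))


def _axis_rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a rotation about a (unit) axis."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    basis = np.eye(3)
    return np.column_stack(
        [_rotate_about_axis(basis[:, k], axis, angle_rad) for k in range(3)])


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180° about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Build the trajectory, parameters and ground-truth manifest of a spec.

    Contact schedules use exact counts (round(population·frames), frames
    chosen by seeded shuffle) so designed populations are recovered exactly;
    hydrogen-bond and ring-pair geometries carry Gaussian jitter around
    their designed means; every designed value is recorded in the manifest.
    """
    spec.validate()
    top, index = _build_topology(spec)
    base = _base_coordinates(spec, top, index)
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames

    # per-directive contact schedules: exactly round(p·F) contact frames
    schedules: list[np.ndarray] = []
    for d in spec.contacts:
        n_contact = int(round(d.population * n_frames))
        sched = np.zeros(n_frames, dtype=bool)
        sched[rng.permutation(n_frames)[:n_contact]] = True
        schedules.append(sched)

    sigma_of = {key: spec.sigma.get(key, spec.default_sigma)
                for key in index}
    res_atoms = [top.atoms_of_residue(ri) for ri in range(top.n_residues)]
    name_idx: dict[tuple[ResidueKey, str], int] = {}
    for key, ri in index.items():
        for ai in res_atoms[ri]:
            name_idx[(key, top.atoms[ai].name)] = int(ai)

    def ring_indices(key: ResidueKey) -> np.ndarray:
        return np.array([name_idx[(key, n)] for n, _ in _RING_ATOMS])

    frames: list[Frame] = []
    box = np.array(spec.box, dtype=float) if spec.box is not None else None
    for f in range(n_frames):
        coords = base.copy()
        # 1. per-residue isotropic Gaussian jitter (rigid per-residue shift)
        for chain in spec.chains:
            for i in range(len(chain.residue_names)):
                key = (chain.chain_id, i + 1)
                shift = rng.normal(0.0, 1.0, 3) * sigma_of[key]
                coords[res_atoms[index[key]]] += shift
        # 2. contact directives: place mobile residue at the scheduled CA–CA
        #    separation along z from the anchor
        for d, sched in zip(spec.contacts, schedules):
            dist = d.contact_distance if sched[f] else d.apart_distance
            ca_a = coords[name_idx[(d.anchor, "CA")]]
            ca_b = coords[name_idx[(d.mobile, "CA")]]
            target = ca_a + np.array([0.0, 0.0, dist])
            coords[res_atoms[index[d.mobile]]] += target - ca_b
        # 3. ring-pair directives: rebuild the mobile ring at the designed
        #    COM separation (along the anchor normal, +z) and interplanar
        #    angle; translate the mobile backbone with the ring
        for rp in spec.ring_pairs:
            d_com = rng.normal(rp.mean_com_distance, rp.com_sigma)
            theta = rng.normal(rp.mean_angle_deg, rp.angle_sigma_deg)
            theta_f = np.radians(180.0 - theta if theta > 90.0 else abs(theta))
            ra = ring_indices(rp.anchor)
            rb = ring_indices(rp.mobile)
            com_a = coords[ra].mean(axis=0)
            com_b_target = com_a + np.array([0.0, 0.0, d_com])
            backbone_b = np.array([i for i in res_atoms[index[rp.mobile]]
                                   if i not in set(rb)])
            coords[backbone_b] += com_b_target - coords[rb].mean(axis=0)
            normal_b = np.array([np.sin(theta_f), 0.0, np.cos(theta_f)])
            p = np.array([np.cos(theta_f), 0.0, -np.sin(theta_f)])  # ⊥ normal
            q = np.array([0.0, 1.0, 0.0])
            for (name, ang_deg) in _RING_ATOMS:
                ang = np.radians(ang_deg)
                coords[name_idx[(rp.mobile, name)]] = (
                    com_b_target
                    + _RING_RADIUS * (np.cos(ang) * p + np.sin(ang) * q))
        # 4. hydrogen-bond directives: reposition (rigid rotation +
        #    translation) the mobile partner so that N–H···O=C is collinear
        #    up to the angle jitter: H···O distance d, D–H···A angle
        #    180° − |α|, with the donor approaching the acceptor's O on the
        #    side opposite its carbonyl carbon.  Directive residues are
        #    never rotated by other directives, so the fixed partner keeps
        #    its template orientation at this point.
        for hb in spec.hbonds:
            d_ha = rng.normal(hb.mean_distance, hb.distance_sigma)
            alpha = np.radians(rng.normal(0.0, hb.angle_sigma_deg))
            w_t = np.array([0.2, -1.2, 0.0])  # template O−C direction
            w_t /= np.linalg.norm(w_t)
            h = coords[name_idx[(hb.donor, "H")]]
            o = coords[name_idx[(hb.acceptor, "O")]]
            # the mobile residue is additionally spun 90° about the bond
            # axis so the rest of its backbone swings out of the partner's
            # plane (otherwise its own carbonyl would sit next to the
            # partner's amide hydrogen and fake a second, reciprocal bond)
            if hb.mobile == "donor":
                e = -w_t  # N→H→O axis, pointing away from the carbonyl C
                e_j = _rotate_about_axis(e, np.cross(e, [0.0, 0.0, 1.0]), alpha)
                h_target = o - d_ha * e_j
                rot = _rotation_between(_NH_DIRECTION, e)
                spin = _axis_rotation_matrix(e, np.pi / 2)
                don = res_atoms[index[hb.donor]]
                coords[don] = (coords[don] - h) @ (spin @ rot).T + h_target
            else:
                e = _NH_DIRECTION  # donor keeps template orientation
                e_j = _rotate_about_axis(e, np.cross(e, [0.0, 0.0, 1.0]), alpha)
                o_target = h + d_ha * e_j
                rot = _rotation_between(w_t, -e)
                spin = _axis_rotation_matrix(e, np.pi / 2)
                acc = res_atoms[index[hb.acceptor]]
                coords[acc] = (coords[acc] - o) @ (spin @ rot).T + o_target
        # 5. optional global rigid-body motion (removed later by alignment)
        if spec.rigid_body_motion:
            rot = _random_rotation(rng)
            trans = rng.normal(0.0, 2.0, 3)
            centroid = coords.mean(axis=0)
            coords = (coords - centroid) @ rot.T + centroid + trans
        frames.append(Frame(coordinates=coords, box=box))

    traj = Trajectory(topology=top, frames=frames)
    params = default_toy_params(top)
    serial_of = {key: top.residues[ri].serial_index
                 for key, ri in index.items()}
    ring_set = set(spec.ring_residues) | {rp.anchor for rp in spec.ring_pairs} \
        | {rp.mobile for rp in spec.ring_pairs}
    extra_templates = {
        top.residues[index[key]].name: [n for n, _ in _RING_ATOMS]
        for key in ring_set
    }
    manifest = {
        "seed": spec.seed,
        "n_frames": n_frames,
        "contacts": [
            {"pair": tuple(sorted((serial_of[d.anchor], serial_of[d.mobile]))),
             "population": int(round(d.population * n_frames)) / n_frames,
             "requested_population": d.population}
            for d in spec.contacts
        ],
        "hbonds": [
            {"donor_serial": serial_of[hb.donor],
             "acceptor_serial": serial_of[hb.acceptor],
             "mean_distance": hb.mean_distance,
             "distance_sigma": hb.distance_sigma,
             "donor_h_selection": f"{hb.donor[0]}:{hb.donor[1]}:H",
             "acceptor_o_selection": f"{hb.acceptor[0]}:{hb.acceptor[1]}:O"}
            for hb in spec.hbonds
        ],
        "ring_pairs": [
            {"pair": tuple(sorted((serial_of[rp.anchor], serial_of[rp.mobile]))),
             "mean_com_distance": rp.mean_com_distance,
             "com_sigma": rp.com_sigma,
             "mean_angle_deg": rp.mean_angle_deg,
             "selection_a": f"ring:{rp.anchor[0]}:{rp.anchor[1]}",
             "selection_b": f"ring:{rp.mobile[0]}:{rp.mobile[1]}"}
            for rp in spec.ring_pairs
        ],
        "sigma": {serial_of[k]: v for k, v in sigma_of.items()},
        "expected_rmsf": {serial_of[k]: v * np.sqrt(3.0)
                          for k, v in sigma_of.items()
                          if k not in spec.mobile_keys()},
        "mobile_serials": sorted(serial_of[k] for k in spec.mobile_keys()),
        "extra_ring_templates": extra_templates,
    }
    return FixtureResult(trajectory=traj, params=params, manifest=manifest)


#: per-atom-name toy nonbonded parameters (charge e, sigma Å, epsilon kcal/mol);
#: backbone charges are AMBER-like, ring carbons are small and neutral-ish
_TOY_PARAMS = {
    "N": (-0.4157, 3.25, 0.17),
    "H": (0.2719, 1.07, 0.0157),
    "CA": (0.0337, 3.40, 0.1094),
    "C": (0.5973, 3.40, 0.086),
    "O": (-0.5679, 2.96, 0.21),
}
_TOY_RING_PARAM = (-0.013, 3.40, 0.086)


def default_toy_params(top: Topology) -> NonbondedParams:
    """Nonbonded parameters for toy topologies, keyed by atom name, with
    the default intra-residue + peptide-bridge exclusion scheme."""
    n = top.n_atoms
    q = np.zeros(n)
    sig = np.zeros(n)
    eps = np.zeros(n)
    for i, atom in enumerate(top.atoms):
        q[i], sig[i], eps[i] = _TOY_PARAMS.get(atom.name, _TOY_RING_PARAM)
    return NonbondedParams(charge=q, sigma=sig, epsilon=eps,
                           exclusions=default_exclusions(top))


def insulin_like_pair(seed: int, n_frames: int = 1000
                      ) -> tuple[FixtureResult, FixtureResult, dict]:
    """Reference/variant toy pair emulating the native-vs-conjugated insulin
    comparison.

    Both systems are 51-residue two-chain peptides (21-residue A chain,
    30-residue B chain, serials 1–51 chain-concatenated).  The variant's
    B29 lysine is replaced by a ring-bearing conjugate residue ("KFP") and
    gains three designed features absent from the reference: a T-shaped
    aromatic ring pair with A19 (COM ≈ 5 Å, angle ≈ 90°), a backbone
    C=O···H–N hydrogen bond to A3 (H···O ≈ 2 Å), and a strengthened
    B28–A4 contact (population 0.9 vs 0.1).  Terminal residues A1, A2, B26
    and B30 fluctuate with σ = 0.25 Å in the variant vs 0.5 Å in the
    reference (designed RMSF ratio 0.5); all other residues use σ = 0.15 Å.
    """
    a_seq = list(INSULIN_A_SEQUENCE)
    b_ref = list(INSULIN_B_SEQUENCE)
    b_var = list(INSULIN_B_SEQUENCE)
    b_var[28] = "KFP"  # B29 lysine–phenylalanine conjugate (synthetic stand-in)

    terminals = [("A", 1), ("A", 2), ("B", 26), ("B", 30)]
    sigma_ref = {k: 0.5 for k in terminals}
    sigma_var = {k: 0.25 for k in terminals}

    common = dict(n_frames=n_frames, default_sigma=0.15,
                  rigid_body_motion=True)
    ref_spec = FixtureSpec(
        chains=[ChainSpec("A", a_seq), ChainSpec("B", b_ref)],
        seed=seed,
        contacts=[ContactDirective(anchor=("A", 4), mobile=("B", 28),
                                   population=0.1)],
        ring_residues=[("A", 19)],
        sigma=sigma_ref,
        **common,
    )
    var_spec = FixtureSpec(
        chains=[ChainSpec("A", a_seq), ChainSpec("B", b_var)],
        seed=seed + 1,
        contacts=[ContactDirective(anchor=("A", 4), mobile=("B", 28),
                                   population=0.9)],
        ring_pairs=[RingPairDirective(anchor=("A", 19), mobile=("B", 29))],
        hbonds=[HBondDirective(donor=("A", 3), acceptor=("B", 29),
                               mobile="donor")],
        sigma=sigma_var,
        **common,
    )
    reference = generate_fixture(ref_spec)
    variant = generate_fixture(var_spec)

    manifest = {
        "n_frames": n_frames,
        "seed": seed,
        "delta_positive_pairs": [(3, 50), (19, 50), (4, 49)],
        "b28_a4_delta_population": 0.9 - 0.1,
        "terminal_serials": [1, 2, 47, 51],
        "terminal_sigma_ratio": 0.25 / 0.5,
        "hbond_peak_A": 2.0,
        "ring_peak_A": 5.0,
        "hbond_selection": ("B:29:O", "A:3:H"),
        "ring_selection": ("ring:B:29", "ring:A:19"),
        "extra_ring_templates": {"KFP": [n for n, _ in _RING_ATOMS]},
        "reference": reference.manifest,
        "variant": variant.manifest,
    }
    return reference, variant, manifest


def _flatten(prefix: str, obj, out: list[tuple[str, str]]) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, out)
    else:
        out.append((prefix, repr(obj) if isinstance(obj, str) else str(obj)))


def write_manifest_tsv(manifest: dict, path: Union[str, Path]) -> None:
    """Flatten a ground-truth manifest to two-column TSV (key, value)."""
    rows: list[tuple[str, str]] = []
    _flatten("", manifest, rows)
    Path(path).write_text(
        "key\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n")
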