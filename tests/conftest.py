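import warnings

import numpy as np
import pytest

import trajcontact as tc
from trajcontact.synthetic import (ChainSpec, FixtureSpec, HBondDirective,
                                   RingPairDirective, generate_fixture)

# toy ring templates produce "ring skipped" warnings for undecorated
# aromatic residues; that is designed behaviour, not a test failure
warnings.filterwarnings("ignore", message=".*ring skipped.*")


@pytest.fixture(scope="session")
def insulin_pair():
    """Reference/variant insulin-like toy pair (200 frames, fixed seed)."""
    return tc.insulin_like_pair(7, n_frames=200)


@pytest.fixture(scope="session")
def interaction_fixture():
    """Small two-chain fixture with one designed H-bond and one designed
    T-shaped ring pair, plus mild jitter (42 atoms, 20 frames)."""
    spec = FixtureSpec(
        chains=[ChainSpec("A", ["ALA", "ALA", "ALA"]),
                ChainSpec("B", ["ALA", "ALA", "ALA"])],
        n_frames=20, seed=3,
        ring_pairs=[RingPairDirective(anchor=("A", 1), mobile=("B", 1))],
        hbonds=[HBondDirective(donor=("B", 3), acceptor=("A", 3),
                               mobile="donor")],
        default_sigma=0.05,
    )
    return generate_fixture(spec)


def make_topology(spec):
    """Hand-build a topology from [(name, element, chain, resnum, resname)]
    rows; atoms of one residue must be contiguous."""
    atoms, residues = [], []
    key = None
    for serial, (name, element, chain, resnum, resname) in enumerate(spec, 1):
        if key != (chain, resnum, resname):
            residues.append(tc.Residue(name=resname, chain_id=chain,
                                       author_number=resnum,
                                       serial_index=len(residues) + 1))
            key = (chain, resnum, resname)
        atoms.append(tc.Atom(serial=serial, name=name, element=element,
                             residue_index=len(residues) - 1))
    return tc.Topology(atoms=atoms, residues=residues)


@pytest.fixture
def make_top():
    return make_topology


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
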