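"""Hydrogen-bond and π-π detection against exhaustive brute-force oracles."""

import math

import numpy as np
import pytest

import trajcontact as tc
from trajcontact.interactions import (HBondCriteria, classify_pipi,
                                      count_interactions, detect_hbonds,
                                      find_aromatic_rings)


def brute_force_hbonds(frame, top, criteria):
    """Plain triple-loop reimplementation of the geometric H-bond rule."""
    coords = frame.coordinates
    no_idx = [i for i, a in enumerate(top.atoms)
              if not a.is_hydrogen and a.element in ("N", "O")]
    out = set()
    for h, atom in enumerate(top.atoms):
        if not atom.is_hydrogen:
            continue
        donor, best = None, 1.2
        for d in no_idx:
            dist = math.dist(coords[h], coords[d])
            if dist <= best:
                donor, best = d, dist
        if donor is None:
            continue
        for acc in no_idx:
            if acc == donor:
                continue
            if top.atoms[acc].residue_index == top.atoms[donor].residue_index:
                continue
            ha = math.dist(coords[h], coords[acc])
            da = math.dist(coords[donor], coords[acc])
            v1 = coords[donor] - coords[h]
            v2 = coords[acc] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ha <= criteria.max_ha_distance and \
                    da <= criteria.max_da_distance and \
                    ang >= criteria.min_dha_angle:
                out.add((donor, h, acc))
    return out


def linear_hbond_frame(make_top, ha=2.0, angle_deg=180.0):
    """N–H···O with prescribed H···O distance and D–H···A angle."""
    top = make_top([("N", "N", "A", 1, "GLY"), ("H", "H", "A", 1, "GLY"),
                    ("C", "C", "A", 2, "GLY"), ("O", "O", "A", 2, "GLY")])
    h = np.array([1.01, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    o = h + ha * np.array([math.cos(theta), math.sin(theta), 0.0])
    coords = np.array([[0.0, 0, 0], h, o + [1.2, 0.6, 0.0], o])
    return top, tc.Frame(coords)


class TestHBondDetection:
    def test_linear_geometry_detected(self, make_top):
        top, frame = linear_hbond_frame(make_top)
        recs = detect_hbonds(frame, top)
        assert len(recs) == 1
        assert recs[0].ha_distance == pytest.approx(2.0, abs=1e-9)
        assert recs[0].dha_angle == pytest.approx(180.0, abs=1e-6)

    def test_bent_geometry_rejected(self, make_top):
        top, frame = linear_hbond_frame(make_top, angle_deg=90.0)
        assert detect_hbonds(frame, top) == []

    def test_criteria_boundaries(self, make_top):
        crit = HBondCriteria(max_ha_distance=2.5)
        top, frame = linear_hbond_frame(make_top, ha=2.49)
        assert len(detect_hbonds(frame, top, crit)) == 1
        top, frame = linear_hbond_frame(make_top, ha=2.51)
        assert detect_hbonds(frame, top, crit) == []

    def test_no_hydrogens_is_informative_error(self, make_top):
        top = make_top([("N", "N", "A", 1, "GLY"), ("O", "O", "A", 2, "GLY")])
        frame = tc.Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(frame, top)

    def test_matches_brute_force_on_jittered_fixture(self, interaction_fixture):
        traj = interaction_fixture.trajectory
        assert traj.n_atoms <= 100
        crit = HBondCriteria()
        for k, frame in enumerate(traj.frames):
            got = {(r.donor, r.hydrogen, r.acceptor)
                   for r in detect_hbonds(frame, traj.topology, crit, k)}
            assert got == brute_force_hbonds(frame, traj.topology, crit)

    def test_tightening_criteria_is_monotone(self, interaction_fixture):
        traj = interaction_fixture.trajectory
        loose = HBondCriteria(2.8, 110.0, 3.8)
        tight = HBondCriteria(2.2, 140.0, 3.2)
        for frame in traj.frames[:5]:
            n_loose = len(detect_hbonds(frame, traj.topology, loose))
            n_tight = len(detect_hbonds(frame, traj.topology, tight))
            assert n_tight <= n_loose

    def test_invariant_under_rigid_motion(self, interaction_fixture, make_top):
        from .conftest import random_rotation
        traj = interaction_fixture.trajectory
        frame = traj.frames[0]
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        moved = tc.Frame(frame.coordinates @ rot.T + np.array([3.0, -5.0, 11.0]))
        a = {(r.donor, r.hydrogen, r.acceptor)
             for r in detect_hbonds(frame, traj.topology)}
        b = {(r.donor, r.hydrogen, r.acceptor)
             for r in detect_hbonds(moved, traj.topology)}
        assert a == b


def ideal_ring(center, normal, radius=1.39):
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(normal, ref)
    p /= np.linalg.norm(p)
    q = np.cross(normal, p)
    ang = np.radians(np.arange(0, 360, 60))
    return center + radius * (np.cos(ang)[:, None] * p + np.sin(ang)[:, None] * q)


def two_ring_system(make_top, com_distance, angle_deg):
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    rows = [(n, "C", "A", 1, "PHE") for n in names] + \
        [(n, "C", "A", 2, "PHE") for n in names]
    top = make_top(rows)
    n2 = np.array([math.sin(math.radians(angle_deg)), 0.0,
                   math.cos(math.radians(angle_deg))])
    coords = np.vstack([ideal_ring(np.zeros(3), [0, 0, 1]),
                        ideal_ring(np.array([0.0, 0.0, com_distance]), n2)])
    rings = find_aromatic_rings(top)
    return top, tc.Frame(coords), rings


class TestAromaticRings:
    def test_templates(self, make_top):
        phe = make_top([(n, "C", "A", 1, "PHE")
                        for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")])
        assert len(find_aromatic_rings(phe)) == 1
        trp_names = ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")
        trp = make_top([(n, "N" if n.startswith("N") else "C", "A", 1, "TRP")
                        for n in trp_names])
        assert len(find_aromatic_rings(trp)) == 2
        gly = make_top([("CA", "C", "A", i, "GLY") for i in (1, 2, 3)])
        assert find_aromatic_rings(gly) == []

    def test_incomplete_ring_skipped_with_warning(self, make_top):
        partial = make_top([(n, "C", "A", 1, "PHE") for n in ("CG", "CD1")])
        with pytest.warns(UserWarning, match="skipped"):
            assert find_aromatic_rings(partial) == []

    def test_extra_template_for_nonstandard_residue(self, make_top):
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        conj = make_top([(n, "C", "B", 29, "KFP") for n in names])
        assert find_aromatic_rings(conj) == []
        rings = find_aromatic_rings(conj, {"KFP": list(names)})
        assert len(rings) == 1


class TestPiPiClassification:
    @pytest.mark.parametrize("dist,angle,expected", [
        (5.0, 90.0, "T-shaped"),
        (3.8, 0.0, "parallel"),
        (5.5, 45.0, "oblique"),
    ])
    def test_angle_classes(self, make_top, dist, angle, expected):
        top, frame, rings = two_ring_system(make_top, dist, angle)
        rec = classify_pipi(rings[0], rings[1], frame, top)
        assert rec is not None
        assert rec.interaction_class == expected
        assert rec.com_distance == pytest.approx(dist, abs=1e-9)
        assert rec.interplanar_angle == pytest.approx(min(angle, 180 - angle),
                                                      abs=1e-6)

    def test_beyond_cutoff_returns_none(self, make_top):
        top, frame, rings = two_ring_system(make_top, 8.0, 90.0)
        assert classify_pipi(rings[0], rings[1], frame, top) is None

    def test_symmetric_in_ring_order(self, make_top):
        top, frame, rings = two_ring_system(make_top, 5.2, 72.0)
        r1 = classify_pipi(rings[0], rings[1], frame, top)
        r2 = classify_pipi(rings[1], rings[0], frame, top)
        assert r1.com_distance == pytest.approx(r2.com_distance, abs=1e-12)
        assert r1.interplanar_angle == pytest.approx(r2.interplanar_angle,
                                                     abs=1e-9)
        assert r1.interaction_class == r2.interaction_class
        assert (r1.residue_a, r1.residue_b) == (r2.residue_a, r2.residue_b)


class TestInteractionCounts:
    def test_static_frames_give_identical_counts(self, interaction_fixture):
        traj = interaction_fixture.trajectory
        static = tc.Trajectory(topology=traj.topology,
                               frames=[traj.frames[0]] * 10)
        counts = count_interactions(
            static,
            extra_ring_templates=interaction_fixture.manifest[
                "extra_ring_templates"])
        assert len(set(counts.hbond_counts)) == 1
        assert len(set(counts.pipi_counts)) == 1

    def test_designed_fixture_counts_one_each(self):
        from trajcontact.synthetic import (ChainSpec, FixtureSpec,
                                           HBondDirective, RingPairDirective,
                                           generate_fixture)
        spec = FixtureSpec(
            chains=[ChainSpec("A", ["ALA"] * 3), ChainSpec("B", ["ALA"] * 3)],
            n_frames=10, seed=9,
            ring_pairs=[RingPairDirective(anchor=("A", 1), mobile=("B", 1),
                                          com_sigma=0.0, angle_sigma_deg=0.0)],
            hbonds=[HBondDirective(donor=("B", 3), acceptor=("A", 3),
                                   mobile="donor", distance_sigma=0.0,
                                   angle_sigma_deg=0.0)],
        )
        fx = generate_fixture(spec)
        counts = count_interactions(
            fx.trajectory,
            extra_ring_templates=fx.manifest["extra_ring_templates"])
        assert np.array_equal(counts.hbond_counts, np.ones(10, dtype=int))
        assert np.array_equal(counts.pipi_counts, np.ones(10, dtype=int))
        assert counts.mean_hbonds == 1.0 and counts.mean_pipi == 1.0

    def test_counts_match_per_frame_redetection(self, interaction_fixture):
        fx = interaction_fixture
        traj = fx.trajectory
        ert = fx.manifest["extra_ring_templates"]
        counts = count_interactions(traj, extra_ring_templates=ert)
        for k, frame in enumerate(traj.frames):
            assert counts.hbond_counts[k] == len(
                detect_hbonds(frame, traj.topology, HBondCriteria(), k))
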