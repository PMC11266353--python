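"""Contact detection, population maps and difference maps."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import trajcontact as tc
from trajcontact.contacts import (contact_population, contacts_of_residue,
                                  diff_contact_map, frame_contacts)
from trajcontact.synthetic import (ChainSpec, ContactDirective, FixtureSpec,
                                   generate_fixture)


def two_residue_frame(make_top, separation):
    """Two single-heavy-atom residues plus close hydrogens."""
    top = make_top([("CA", "C", "A", 1, "GLY"), ("HA", "H", "A", 1, "GLY"),
                    ("CA", "C", "A", 2, "GLY"), ("HA", "H", "A", 2, "GLY")])
    coords = np.array([[0.0, 0, 0], [separation / 2 - 0.9, 0, 0],
                       [separation, 0, 0], [separation / 2 + 0.9, 0, 0]])
    return top, tc.Frame(coords)


def brute_force_contact_map(traj, cutoff=4.5):
    """Independent per-frame heavy-atom double-loop recount."""
    top = traj.topology
    heavy = [i for i, a in enumerate(top.atoms) if not a.is_hydrogen]
    res_of = np.array([top.atoms[i].residue_index for i in heavy])
    r = top.n_residues
    acc = np.zeros((r, r))
    for frame in traj.frames:
        d = cdist(frame.coordinates[heavy], frame.coordinates[heavy])
        hit = np.zeros((r, r), dtype=bool)
        for a in range(len(heavy)):
            for b in range(a + 1, len(heavy)):
                if res_of[a] != res_of[b] and d[a, b] <= cutoff:
                    hit[res_of[a], res_of[b]] = True
                    hit[res_of[b], res_of[a]] = True
        acc += hit
    return acc / traj.n_frames


class TestFrameContacts:
    def test_cutoff_boundary(self, make_top):
        top, frame = two_residue_frame(make_top, 4.4)
        assert frame_contacts(frame, top) == {(1, 2)}
        top, frame = two_residue_frame(make_top, 4.6)
        assert frame_contacts(frame, top) == set()

    def test_hydrogens_do_not_create_contacts(self, make_top):
        # hydrogens 1.8 Å apart while heavy atoms are 6 Å apart
        top, frame = two_residue_frame(make_top, 6.0)
        h_dist = np.linalg.norm(frame.coordinates[1] - frame.coordinates[3])
        assert h_dist < 2.0
        assert frame_contacts(frame, top) == set()

    def test_minimum_image_used_with_box(self, make_top):
        top = make_top([("CA", "C", "A", 1, "GLY"), ("CA", "C", "A", 2, "GLY")])
        frame = tc.Frame(np.array([[0.5, 5.0, 5.0], [9.5, 5.0, 5.0]]),
                         box=[10.0, 10.0, 10.0])
        assert frame_contacts(frame, top) == {(1, 2)}  # 1 Å across boundary

    def test_monotone_in_cutoff(self, insulin_pair):
        ref, _, _ = insulin_pair
        frame = ref.trajectory.frames[0]
        top = ref.trajectory.topology
        small = frame_contacts(frame, top, cutoff=4.0)
        large = frame_contacts(frame, top, cutoff=6.0)
        assert small <= large


class TestContactPopulation:
    def fixture_with_populations(self, populations, n_frames, seed=5):
        chains = [ChainSpec("A", ["GLY"] * len(populations)),
                  ChainSpec("B", ["GLY"] * len(populations))]
        directives = [ContactDirective(anchor=("A", i + 1), mobile=("B", i + 1),
                                       population=p)
                      for i, p in enumerate(populations)]
        return generate_fixture(FixtureSpec(chains=chains, n_frames=n_frames,
                                            seed=seed, contacts=directives))

    @pytest.mark.parametrize("n_frames", [10, 100, 1000])
    def test_designed_populations_recovered_exactly(self, n_frames):
        pops = [0.0, 0.3, 0.7, 1.0]
        fx = self.fixture_with_populations(pops, n_frames)
        cmap = contact_population(fx.trajectory)
        for entry, p in zip(fx.manifest["contacts"], pops):
            i, j = entry["pair"]
            assert cmap.values[i - 1, j - 1] == pytest.approx(
                round(p * n_frames) / n_frames, abs=0)

    def test_matches_brute_force_recount(self):
        fx = self.fixture_with_populations([0.25, 0.6], 40)
        cmap = contact_population(fx.trajectory)
        oracle = brute_force_contact_map(fx.trajectory)
        assert np.array_equal(cmap.values, oracle)

    def test_single_frame_values_are_binary(self, insulin_pair):
        ref, _, _ = insulin_pair
        traj = tc.Trajectory(topology=ref.trajectory.topology,
                             frames=[ref.trajectory.frames[0]])
        cmap = contact_population(traj)
        assert set(np.unique(cmap.values)) <= {0.0, 1.0}

    def test_population_is_mean_of_frame_indicators(self):
        fx = self.fixture_with_populations([0.5], 20)
        traj = fx.trajectory
        top = traj.topology
        r = top.n_residues
        acc = np.zeros((r, r))
        for frame in traj.frames:
            for i, j in frame_contacts(frame, top):
                acc[i - 1, j - 1] += 1
                acc[j - 1, i - 1] += 1
        assert np.array_equal(contact_population(traj).values,
                              acc / traj.n_frames)


class TestDiffContactMap:
    def test_designed_difference_and_antisymmetry(self, insulin_pair):
        ref, var, manifest = insulin_pair
        c_ref = contact_population(ref.trajectory)
        c_var = contact_population(var.trajectory)
        delta = diff_contact_map(c_var, c_ref)
        i, j = 4, 49  # strengthened B28–A4 contact
        assert delta.values[i - 1, j - 1] == pytest.approx(
            manifest["b28_a4_delta_population"], abs=1e-12)
        swapped = diff_contact_map(c_ref, c_var)
        assert np.array_equal(swapped.values, -delta.values)

    def test_identical_maps_give_zero(self, insulin_pair):
        ref, _, _ = insulin_pair
        c = contact_population(ref.trajectory)
        assert not np.any(diff_contact_map(c, c).values)

    def test_dimension_mismatch_rejected(self, make_top):
        c1 = tc.ContactMap(values=np.zeros((2, 2)), labels=["a", "b"])
        c2 = tc.ContactMap(values=np.zeros((3, 3)), labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="mismatch"):
            diff_contact_map(c1, c2)


class TestContactsOfResidue:
    def cmap(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.6
        v[0, 3] = v[3, 0] = 0.1
        return tc.ContactMap(values=v, labels=list("abcd"))

    def test_threshold_and_descending_order(self):
        assert contacts_of_residue(self.cmap(), 1, 0.5) == [(2, 0.9), (3, 0.6)]

    def test_zero_threshold_returns_all_nonzero(self):
        assert [p for p, _ in contacts_of_residue(self.cmap(), 1, 0.0)] == \
            [2, 3, 4]

    def test_unreachable_threshold_empty(self):
        assert contacts_of_residue(self.cmap(), 1, 1.0) == []

    def test_out_of_range_serial_rejected(self):
        with pytest.raises(ValueError):
            contacts_of_residue(self.cmap(), 9)
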