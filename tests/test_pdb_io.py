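"""Multi-model PDB round trips, residue numbering and parameter tables."""

import numpy as np
import pytest

import trajcontact as tc
from trajcontact.pdb_io import (PDBParseError, default_exclusions,
                                read_multimodel_pdb, read_params_table,
                                write_multimodel_pdb)
from trajcontact.synthetic import (ChainSpec, FixtureSpec, generate_fixture,
                                   INSULIN_A_SEQUENCE, INSULIN_B_SEQUENCE)
from trajcontact.trajectory import residue_serial_map, TopologyError


def tiny_pdb_text(models=2, atoms=3, drop_last_atom_in=None):
    lines = []
    for m in range(1, models + 1):
        lines.append(f"MODEL     {m:4d}")
        n = atoms - (1 if m == drop_last_atom_in else 0)
        names = ["N", "CA", "C"]
        for i in range(n):
            x = 1.0 * i + 0.1 * m
            lines.append(
                f"ATOM  {i+1:5d}  {names[i]:<3s}ALA A   1    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           "
                f"{names[i][0]}")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestReadWrite:
    def test_two_model_three_atom_parse(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(tiny_pdb_text())
        traj = read_multimodel_pdb(p)
        assert traj.n_frames == 2
        assert traj.n_atoms == 3
        assert traj.topology.atoms[1].name == "CA"

    def test_model_atom_count_mismatch_names_model(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(tiny_pdb_text(models=3, drop_last_atom_in=2))
        with pytest.raises(PDBParseError, match="model 2"):
            read_multimodel_pdb(p)

    def test_unparseable_coordinate_cites_line(self, tmp_path):
        text = tiny_pdb_text(models=1).splitlines()
        text[2] = text[2][:30] + "   xx.xxx" + text[2][39:]
        p = tmp_path / "bad.pdb"
        p.write_text("\n".join(text) + "\n")
        with pytest.raises(PDBParseError, match="line 3"):
            read_multimodel_pdb(p)

    def test_crlf_line_endings(self, tmp_path):
        p = tmp_path / "crlf.pdb"
        p.write_bytes(tiny_pdb_text().replace("\n", "\r\n").encode())
        assert read_multimodel_pdb(p).n_frames == 2

    def test_round_trip_coordinates_and_topology(self, tmp_path, insulin_pair):
        ref, _, _ = insulin_pair
        traj = tc.Trajectory(topology=ref.trajectory.topology,
                             frames=ref.trajectory.frames[:5])
        p = tmp_path / "rt.pdb"
        write_multimodel_pdb(traj, p)
        back = read_multimodel_pdb(p)
        assert back.n_frames == traj.n_frames
        assert [a.name for a in back.topology.atoms] == \
            [a.name for a in traj.topology.atoms]
        assert [r.serial_index for r in back.topology.residues] == \
            [r.serial_index for r in traj.topology.residues]
        for f1, f2 in zip(traj.frames, back.frames):
            # PDB stores 3 decimals
            assert np.allclose(f1.coordinates, f2.coordinates, atol=1.001e-3)

    def test_written_file_readable_by_independent_parser(self, tmp_path,
                                                         insulin_pair):
        gemmi = pytest.importorskip("gemmi")
        ref, _, _ = insulin_pair
        traj = tc.Trajectory(topology=ref.trajectory.topology,
                             frames=ref.trajectory.frames[:3])
        p = tmp_path / "oracle.pdb"
        write_multimodel_pdb(traj, p)
        st = gemmi.read_structure(str(p))
        assert len(st) == 3  # models
        model = st[0]
        n_atoms = sum(len(res) for chain in model for res in chain)
        assert n_atoms == traj.n_atoms
        first = model[0][0][0]
        assert first.pos.x == pytest.approx(
            traj.frames[0].coordinates[0][0], abs=1e-3)

    def test_coordinates_exceeding_field_width_rejected(self, make_top):
        top = make_top([("CA", "C", "A", 1, "ALA")])
        traj = tc.Trajectory(topology=top,
                             frames=[tc.Frame(np.array([[12000.0, 0, 0]]))])
        with pytest.raises(ValueError, match="field width"):
            write_multimodel_pdb(traj, "/dev/null")

    def test_solvent_stripped_by_default(self, tmp_path):
        lines = ["MODEL        1",
                 "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
                 "  1.00  0.00           C",
                 "HETATM    2  O   HOH A 101       5.000   0.000   0.000"
                 "  1.00  0.00           O",
                 "ENDMDL", "END"]
        p = tmp_path / "w.pdb"
        p.write_text("\n".join(lines) + "\n")
        assert read_multimodel_pdb(p).n_atoms == 1
        assert read_multimodel_pdb(p, keep_solvent=True).n_atoms == 2

    def test_orthorhombic_box_parsed_from_cryst1(self, tmp_path):
        text = ("CRYST1   50.000   60.000   70.000  90.00  90.00  90.00 P 1\n"
                + tiny_pdb_text(models=1))
        p = tmp_path / "box.pdb"
        p.write_text(text)
        traj = read_multimodel_pdb(p)
        assert np.allclose(traj.frames[0].box, [50, 60, 70])
        # non-orthorhombic → treated as absent
        p.write_text(text.replace(" 90.00  90.00  90.00",
                                  " 90.00  90.00 120.00"))
        assert read_multimodel_pdb(p).frames[0].box is None


class TestResidueSerialMap:
    def insulin_topology(self):
        spec = FixtureSpec(chains=[ChainSpec("A", list(INSULIN_A_SEQUENCE)),
                                   ChainSpec("B", list(INSULIN_B_SEQUENCE))],
                           n_frames=1, seed=0)
        return generate_fixture(spec).trajectory.topology

    def test_insulin_concatenated_numbering(self):
        m = residue_serial_map(self.insulin_topology())
        assert m[("A", 1)] == 1
        assert m[("A", 21)] == 21
        assert m[("B", 1)] == 22
        assert m[("B", 30)] == 51

    def test_bijection_onto_consecutive_serials(self):
        m = residue_serial_map(self.insulin_topology())
        assert sorted(m.values()) == list(range(1, 52))

    def test_single_chain_identity(self, make_top):
        top = make_top([("CA", "C", "A", i, "GLY") for i in range(1, 6)])
        m = residue_serial_map(top)
        assert all(m[("A", i)] == i for i in range(1, 6))

    def test_author_numbering_gap_stays_consecutive(self, make_top):
        top = make_top([("CA", "C", "A", n, "GLY") for n in (7, 8, 10, 11)])
        m = residue_serial_map(top)
        assert m[("A", 10)] == 3

    def test_duplicate_residue_number_rejected(self, make_top):
        top = make_top([("CA", "C", "A", 1, "GLY"), ("CA", "C", "A", 1, "ALA")])
        with pytest.raises(TopologyError, match="duplicate"):
            residue_serial_map(top)


class TestParamsTable:
    def write_table(self, path, rows):
        header = "chain\tresnum\tatom_name\tq\tsigma\tepsilon"
        path.write_text("\n".join([header] + rows) + "\n")

    def test_full_coverage_and_wildcards(self, tmp_path, make_top):
        top = make_top([("N", "N", "A", 1, "GLY"), ("CA", "C", "A", 1, "GLY"),
                        ("CA", "C", "A", 2, "ALA")])
        p = tmp_path / "p.tsv"
        self.write_table(p, ["A\t1\tN\t-0.4\t3.25\t0.17",
                             "*\t*\tCA\t0.1\t3.4\t0.09"])
        params = read_params_table(p, top)
        assert params.charge[0] == -0.4
        # wildcard row applies to every CA
        assert params.charge[1] == params.charge[2] == 0.1

    def test_exact_row_overrides_wildcard(self, tmp_path, make_top):
        top = make_top([("CA", "C", "A", 1, "GLY"), ("CA", "C", "A", 2, "GLY")])
        p = tmp_path / "p.tsv"
        self.write_table(p, ["*\t*\tCA\t0.1\t3.4\t0.09",
                             "A\t2\tCA\t0.5\t3.4\t0.09"])
        params = read_params_table(p, top)
        assert params.charge[0] == 0.1
        assert params.charge[1] == 0.5

    def test_missing_atom_named_in_error(self, tmp_path, make_top):
        top = make_top([("N", "N", "A", 1, "GLY"), ("CA", "C", "A", 1, "GLY")])
        p = tmp_path / "p.tsv"
        self.write_table(p, ["*\t*\tCA\t0.1\t3.4\t0.09"])
        with pytest.raises(ValueError, match="A1:N"):
            read_params_table(p, top)

    def test_non_numeric_field_cites_row(self, tmp_path, make_top):
        top = make_top([("CA", "C", "A", 1, "GLY")])
        p = tmp_path / "p.tsv"
        self.write_table(p, ["*\t*\tCA\tabc\t3.4\t0.09"])
        with pytest.raises(ValueError, match="row 2"):
            read_params_table(p, top)

    def test_default_exclusions_intra_residue_and_peptide_bridge(self, make_top):
        top = make_top([("N", "N", "A", 1, "GLY"), ("CA", "C", "A", 1, "GLY"),
                        ("C", "C", "A", 1, "GLY"), ("N", "N", "A", 2, "GLY"),
                        ("CB", "C", "A", 2, "GLY")])
        excl = default_exclusions(top)
        assert (0, 1) in excl and (0, 2) in excl          # intra-residue
        assert (2, 3) in excl                             # C(1)–N(2) bridge
        assert (0, 4) not in excl                         # N(1)–CB(2) interacts
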