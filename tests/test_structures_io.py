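"""Structure/trajectory I/O and leaflet/subunit assignment."""

import numpy as np
import pytest

from poremetrics import fileio
from poremetrics.structures import (Atom, Frame, MolecularSystem,
                                    assign_leaflets, assign_subunits,
                                    infer_element)
from poremetrics.synthetic import synth_membrane_patch, synth_ring

MINI_GRO = """\
three atoms
    3
    1POPC    P    1   1.000   2.000   3.000
    1POPC   C2    2   1.100   2.100   3.100
    2SOL    OW    3   5.000   5.000   5.000
  10.00000  10.00000  10.00000
"""

MINI_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A   1      12.700   0.000   5.000  1.00  0.00
ATOM      2  CB  ALA A   1      13.700   1.000   5.000  1.00  0.00
ATOM      3  CA  GLY B   2       1.000   2.000   3.000  1.00  0.00
END
"""


class TestReadStructure:
    def test_minimal_gro(self, tmp_path):
        p = tmp_path / "mini.gro"
        p.write_text(MINI_GRO)
        system, frame = fileio.read_gro(p)
        assert system.n_atoms == 3
        assert frame.n_atoms == 3
        np.testing.assert_allclose(frame.box, [10.0, 10.0, 10.0])
        np.testing.assert_allclose(frame.positions[0], [1.0, 2.0, 3.0])
        assert list(system.species_class) == ["lipid", "water"]

    def test_pdb_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        system, frame = fileio.read_pdb(p)
        assert frame.positions[0, 0] == pytest.approx(1.270)
        np.testing.assert_allclose(frame.box, [10.0, 10.0, 10.0])
        # chains survive and drive subunit assignment
        assign_subunits(system)
        assert list(system.subunit) == [0, 1]

    def test_gro_roundtrip_preserves_coordinates(self, tmp_path):
        system, frame, _ = synth_membrane_patch({"POPC": 30, "CHOL": 10},
                                                {"POPC": 40}, seed=3)
        path = tmp_path / "patch.gro"
        fileio.write_gro(path, system, frame)
        system2, frame2 = fileio.read_gro(path)
        assert system2.n_atoms == system.n_atoms
        # GRO stores 3 decimals (0.001 nm); round-trip is exact at that level
        np.testing.assert_allclose(frame2.positions,
                                   np.round(frame.positions, 3), atol=1e-12)
        assert [a.name for a in system2.atoms] == [a.name for a in system.atoms]

    def test_gro_roundtrip_matches_mdanalysis(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        system, frame, _ = synth_membrane_patch({"POPC": 10}, {"POPC": 10},
                                                seed=5)
        path = tmp_path / "patch.gro"
        fileio.write_gro(path, system, frame)
        u = mda.Universe(str(path))
        np.testing.assert_allclose(u.atoms.positions / 10.0,
                                   np.round(frame.positions, 3), atol=1e-5)

    def test_malformed_columns_name_line(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("title\n    1\n    1POPC    P    1   x.xxx   2.0   3.0\n"
                     "  10.0 10.0 10.0\n")
        with pytest.raises(fileio.ParseError, match="line 3"):
            fileio.read_gro(p)

    def test_missing_box_line(self, tmp_path):
        p = tmp_path / "nobox.gro"
        p.write_text("title\n    1\n    1POPC    P    1   1.000   2.000   3.000\n")
        with pytest.raises(fileio.ParseError, match="box"):
            fileio.read_gro(p)


class TestTrajectory:
    def test_two_frames_in_order(self, tmp_path):
        system, frame, _ = synth_membrane_patch({"POPC": 5}, {"POPC": 5}, seed=1)
        f2 = Frame(time=2.5, positions=frame.positions + 0.1, box=frame.box)
        path = tmp_path / "traj.gro"
        fileio.write_trajectory(path, system, [frame, f2])
        frames = list(fileio.read_trajectory(path))
        assert [f.time for f in frames] == [0.0, 2.5]

    def test_empty_file_yields_nothing(self, tmp_path):
        p = tmp_path / "empty.gro"
        p.write_text("")
        assert list(fileio.read_trajectory(p)) == []

    def test_frame_57_matches_generator(self, tmp_path):
        system, frame, _ = synth_membrane_patch({"POPC": 5}, {"POPC": 5}, seed=2)
        rng = np.random.default_rng(0)
        frames = [Frame(time=float(t), positions=frame.positions + 0.001 * t,
                        box=frame.box) for t in range(100)]
        path = tmp_path / "traj100.gro"
        fileio.write_trajectory(path, system, frames)
        read = list(fileio.read_trajectory(path))
        assert len(read) == 100
        np.testing.assert_allclose(read[57].positions,
                                   np.round(frames[57].positions, 3),
                                   atol=1e-12)

    def test_atom_count_change_raises_with_index(self, tmp_path):
        p = tmp_path / "bad_traj.gro"
        p.write_text(MINI_GRO + MINI_GRO.replace("    3\n", "    2\n", 1)
                     .replace("    2SOL    OW    3   5.000   5.000   5.000\n", ""))
        with pytest.raises(fileio.ParseError, match="frame 1"):
            list(fileio.read_trajectory(p))


class TestLeaflets:
    def test_census_99_100(self, flat_patch):
        system, frame, _ = flat_patch
        inner = (system.leaflet == "inner").sum()
        outer = (system.leaflet == "outer").sum()
        assert (inner, outer) == (99, 100)

    def test_invariant_under_z_translation(self, flat_patch):
        system, frame, _ = flat_patch
        before = system.leaflet.copy()
        shifted = Frame(time=0.0, positions=frame.positions + [0, 0, 3.7],
                        box=frame.box * 2)
        assign_leaflets(system, shifted)
        assert list(system.leaflet) == list(before)

    def test_crown_deformation_preserves_labels(self):
        from poremetrics.structures import assign_leaflets as al
        flat_sys, flat_fr, _ = synth_membrane_patch(
            {"POPC": 80}, {"POPC": 80}, box_xy=30.0, seed=9)
        crown_sys, crown_fr, _ = synth_membrane_patch(
            {"POPC": 80}, {"POPC": 80}, box_xy=30.0, crown_height=2.0,
            ring_radius=10.0, seed=9)
        al(flat_sys, flat_fr)
        al(crown_sys, crown_fr)
        assert list(flat_sys.leaflet) == list(crown_sys.leaflet)

    def test_single_leaflet_warns(self):
        atoms = [Atom("P", "POPC", i + 1) for i in range(4)]
        system = MolecularSystem(atoms)
        frame = Frame(time=0, positions=np.column_stack(
            [np.arange(4), np.arange(4), np.full(4, 5.0)]), box=[10, 10, 10])
        with pytest.warns(UserWarning, match="single leaflet"):
            assign_leaflets(system, frame)

    def test_no_lipids_raises(self):
        system = MolecularSystem([Atom("CA", "ALA", 1)])
        frame = Frame(time=0, positions=[[1, 1, 1]], box=[5, 5, 5])
        with pytest.raises(ValueError, match="no lipid"):
            assign_leaflets(system, frame)


class TestSubunits:
    def test_equal_blocks(self):
        atoms = [Atom("CA", "ALA", i + 1) for i in range(660)]
        system = MolecularSystem(atoms)
        assign_subunits(system, 2)
        assert list(system.subunit[:330]) == [0] * 330
        assert list(system.subunit[330:]) == [1] * 330

    def test_indivisible_raises(self):
        system = MolecularSystem([Atom("CA", "ALA", i + 1) for i in range(7)])
        with pytest.raises(ValueError, match="not divisible"):
            assign_subunits(system, 3)

    def test_ring_generator_truth(self):
        system, frame, truth = synth_ring(16, arc_fraction=16 / 33, seed=0)
        assert list(system.subunit) == truth.params["subunit_of_residue"]
        # labels are a disjoint cover of the protein residues
        prot = system.protein_residues()
        assert set(system.subunit[prot]) == set(range(16))
        assert all(system.subunit[r] >= 0 for r in prot)

    def test_element_inference(self):
        assert infer_element("CA", "ALA") == "C"
        assert infer_element("1H3", "POPC") == "H"
        assert infer_element("NA", "NA") == "Na"
        assert infer_element("CL", "CL") == "Cl"
        assert Atom("P", "POPC", 1).is_heavy
        assert not Atom("HA", "ALA", 1).is_heavy
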