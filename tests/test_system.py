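"""Structure reading, classification, pocket selection, trajectory I/O."""

import io

import numpy as np
import pytest

import mmgbsa_ie as m
from mmgbsa_ie.errors import (
    ClassificationError,
    EmptyInputError,
    MissingParameterError,
    AmbiguousParameterError,
    ParseError,
    TopologyError,
)
from mmgbsa_ie.params import (
    attach_parameters,
    parameter_table_from_system,
    read_parameter_table,
)
from mmgbsa_ie.system import load_trajectory_text, save_trajectory_text

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.100   2.600   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.400   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   1       1.500   0.000   0.000  0.60  0.00           C
ATOM      4  C   SER A   1       2.500   1.000   0.000  1.00  0.00           C
END
"""

LIGAND_PDB = """\
HETATM    1  N1  LIG A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  C1  LIG A   1       1.400   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_toy_counts(self):
        system = m.read_structure(TOY_PDB)
        assert system.n_atoms == 5
        assert len(system.residues) == 2
        assert [r.name for r in system.residues] == ["ALA", "GLY"]
        assert np.allclose(system.reference_coords[1], [1.458, 0, 0])

    def test_altloc_keeps_highest_occupancy(self):
        system = m.read_structure(ALTLOC_PDB)
        assert system.n_atoms == 3  # one CA survives
        ca = [a for a in system.atoms if a.name == "CA"]
        assert len(ca) == 1
        assert np.isclose(system.reference_coords[ca[0].serial][0], 1.5)

    def test_hetatm_only_flags_ligand(self):
        system = m.read_structure(LIGAND_PDB)
        assert len(system.residues) == 1
        assert system.ligand_residue.name == "LIG"

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            m.read_structure("END\n")

    def test_malformed_line(self):
        bad = TOY_PDB.replace("1.458", "xx.xx")
        with pytest.raises(ParseError):
            m.read_structure(bad)


def test_pdb_round_trip(toy):
    """Writing frame 0 and re-reading reproduces names, residue partition
    and coordinates to the PDB's 1e-3 Å precision."""
    system, _ = toy
    text = m.write_pdb(system)
    back = m.read_structure(text)
    assert back.n_atoms == system.n_atoms
    assert [r.name for r in back.residues] == [r.name for r in system.residues]
    assert [(r.atom_start, r.atom_stop) for r in back.residues] == \
           [(r.atom_start, r.atom_stop) for r in system.residues]
    assert [a.name for a in back.atoms] == [a.name for a in system.atoms]
    assert np.abs(back.reference_coords - system.reference_coords).max() <= 1e-3
    assert back.ligand_residue.name == "LIG"


class TestClassifyResidue:
    @pytest.mark.parametrize("name,expected", [
        ("LEU", "nonpolar"), ("GLU", "charged"), ("SER", "polar"),
        ("HIP", "charged"), ("HIE", "polar"), ("CYX", "polar"),
    ])
    def test_examples(self, name, expected):
        assert m.classify_residue(name) == expected

    def test_partitions_all_canonical(self):
        canonical = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
                     "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
                     "THR", "TRP", "TYR", "VAL"]
        classes = {m.classify_residue(n) for n in canonical}
        assert classes == {"nonpolar", "polar", "charged"}

    def test_unknown_raises(self):
        with pytest.raises(ClassificationError):
            m.classify_residue("XYZ")


class TestSelectPocket:
    def _two_residue_system(self, d1, d2):
        text = (
            f"ATOM      1  CB  ALA A   1    {d1:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n"
            f"ATOM      2  CB  ALA A   2    {d2:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n"
            f"HETATM    3  C1  LIG A   3    {0.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n"
            "END\n")
        return m.read_structure(text)

    def test_distance_rule(self):
        system = self._two_residue_system(4.0, 8.0)
        assert m.select_pocket(system, cutoff=5.0) == [0]

    def test_zero_cutoff_empty(self):
        system = self._two_residue_system(4.0, 8.0)
        assert m.select_pocket(system, cutoff=0.0) == []

    def test_monotone_in_cutoff(self, toy):
        system, _ = toy
        pockets = [set(m.select_pocket(system, cutoff=c))
                   for c in (0.5, 2.0, 4.0, 6.0, 10.0)]
        for small, big in zip(pockets, pockets[1:]):
            assert small <= big

    def test_no_ligand_errors(self):
        system = m.read_structure(TOY_PDB)
        with pytest.raises(TopologyError):
            m.select_pocket(system)


class TestParameters:
    def test_attach_full_table(self, toy):
        system, _ = toy
        table = parameter_table_from_system(system).drop(columns="serial")
        bare = m.read_structure(m.write_pdb(system))
        bare.bonds = list(system.bonds)
        # toy templates reuse (residue, atom) keys across copies of the same
        # residue type; collapse to unique keys
        table = table.drop_duplicates(subset=["residue", "atom"])
        full = attach_parameters(bare, table)
        assert all(a.parameterized() for a in full.atoms)

    def test_missing_atom_named(self, toy):
        system, _ = toy
        table = parameter_table_from_system(system)
        table = table[table["atom"] != "OE1"].drop(columns="serial")
        table = table.drop_duplicates(subset=["residue", "atom"])
        bare = m.read_structure(m.write_pdb(system))
        with pytest.raises(MissingParameterError, match="OE1"):
            attach_parameters(bare, table)

    def test_duplicate_key_rejected(self, toy):
        system, _ = toy
        table = parameter_table_from_system(system).drop(columns="serial")
        dup = table.iloc[[0]]
        with pytest.raises(AmbiguousParameterError):
            attach_parameters(system, __import__("pandas").concat([table, dup]))

    def test_csv_round_trip(self, toy, tmp_path):
        system, _ = toy
        path = tmp_path / "params.csv"
        parameter_table_from_system(system).to_csv(path, index=False)
        df = read_parameter_table(path)
        assert list(df.columns)[:7] == [
            "residue", "atom", "charge_e", "rmin_half_A", "epsilon_kcal",
            "gb_radius_A", "gb_screen"]


class TestTrajectory:
    def test_text_round_trip(self, toy, tmp_path):
        _, traj = toy
        path = tmp_path / "traj.txt"
        save_trajectory_text(traj, path)
        back = load_trajectory_text(path)
        assert back.n_frames == traj.n_frames
        assert np.abs(back.coords - traj.coords).max() <= 1e-6
        assert np.allclose(back.times, traj.times)

    def test_unequal_spacing_rejected(self):
        with pytest.raises(ParseError):
            m.Trajectory(coords=np.zeros((3, 1, 3)),
                         times=np.array([0.0, 1.0, 3.0]))

    def test_multi_model_pdb(self, toy):
        system, traj = toy
        from mmgbsa_ie.system import write_trajectory_pdb

        buf = io.StringIO()
        write_trajectory_pdb(system, traj.slice_frames(0, 3), buf)
        back = m.load_trajectory_pdb(io.StringIO(buf.getvalue()), system)
        assert back.n_frames == 3
        assert np.abs(back.coords - traj.coords[:3]).max() <= 1e-3
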