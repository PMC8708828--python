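import numpy as np
import pytest

from memscan.core_model import (AtomRecord, MolecularSystem, ParseError,
                                SelectionError, Trajectory, combine_systems,
                                read_params, read_structure, read_trajectory,
                                select_atoms, write_params, write_pqr,
                                write_structure, write_trajectory)
from memscan.synthetic_systems import (FluctuationSpec, default_param_table,
                                       make_trajectory)


def tiny_system(charges=False):
    atoms = [
        AtomRecord(1, "P", "LIP", 1, "M", "P", [0.0, 0.0, 19.5]),
        AtomRecord(2, "C1", "LIP", 1, "M", "C", [0.0, 0.0, 15.5]),
        AtomRecord(3, "CA", "SER", 2, "P", "C", [1.0, 2.0, 3.0]),
        AtomRecord(4, "C9", "LIG", 3, "L", "C", [4.0, 5.0, 6.0]),
        AtomRecord(5, "FE", "FE2", 4, "L", "Fe", [7.0, 8.0, 9.0]),
    ]
    if charges:
        for a, q in zip(atoms, (-0.8, 0.4, -0.1, 0.05, 2.0)):
            a.charge = q
            a.lj_rmin = 1.7
            a.lj_epsilon = 0.3
    return MolecularSystem(atoms, groups={"ligand": [3], "protein": [2]})


class TestStructureIO:
    def test_pdb_round_trip_preserves_names_and_coords(self, tmp_path):
        system = tiny_system()
        path = tmp_path / "tiny.pdb"
        write_structure(system, path)
        back = read_structure(path)
        assert back.n_atoms == 5
        assert list(back.names) == ["P", "C1", "CA", "C9", "FE"]
        np.testing.assert_allclose(back.coords, system.coords, atol=1e-3)

    def test_pqr_round_trip_carries_charge_and_radius(self, tmp_path):
        system = tiny_system(charges=True)
        system.charges[0] = -0.8
        system.lj_rmin[0] = 1.7
        path = tmp_path / "tiny.pqr"
        write_pqr(system, path)
        back = read_structure(path, format="pqr")
        assert back.atom(0).charge == pytest.approx(-0.8)
        assert back.atom(0).lj_rmin == pytest.approx(1.7)

    def test_generated_fixture_round_trips(self, tmp_path, membrane_fixture):
        system, manifest = membrane_fixture
        path = tmp_path / "fix.pdb"
        write_structure(system, path)
        back = read_structure(path)
        assert back.n_atoms == manifest["bilayer"]["n_atoms"] + \
            manifest["protein"]["n_atoms"]
        np.testing.assert_allclose(back.coords, system.coords, atol=1e-3)

    def test_zero_atom_and_missing_file_errors(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(ParseError):
            read_structure(empty)
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestTrajectoryIO:
    def test_dcd_round_trip(self, tmp_path, membrane_fixture):
        system, _ = membrane_fixture
        n_res = len(system.residue_index_map())
        traj, _ = make_trajectory(system, FluctuationSpec(
            per_residue_sigma=[0.4] * n_res, n_frames=50, seed=1))
        path = tmp_path / "t.dcd"
        write_trajectory(traj, path)
        back = read_trajectory(path, system)
        assert back.n_frames == 50
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)
        np.testing.assert_allclose(np.diff(back.times), 2.0, atol=1e-6)

    def test_multimodel_pdb_frames(self, tmp_path):
        system = tiny_system()
        frames = np.stack([system.coords + i for i in range(3)])
        traj = Trajectory(system=system, frames=frames,
                          times=np.arange(3.0))
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, system)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, frames, atol=1e-3)

    def test_single_frame_structure_as_trajectory(self, tmp_path):
        system = tiny_system()
        traj = Trajectory(system=system, frames=system.coords[None],
                          times=np.zeros(1))
        path = tmp_path / "one.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, system)
        assert back.n_frames == 1
        np.testing.assert_allclose(back.frames[0], system.coords, atol=1e-3)

    def test_atom_count_mismatch_names_both_counts(self, tmp_path):
        system = tiny_system()
        traj = Trajectory(system=system, frames=system.coords[None],
                          times=np.zeros(1))
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        other = MolecularSystem([AtomRecord(1, "CA", "SER", 1, "A", "C",
                                            [0, 0, 0])])
        with pytest.raises(ParseError, match="5.*1|1.*5"):
            read_trajectory(path, other)


class TestParams:
    def test_round_trip_and_lookup(self, tmp_path):
        table = default_param_table()
        path = tmp_path / "params.tsv"
        write_params(table, path)
        back = read_params(path)
        assert len(back) == len(table)
        assert back[("LIP", "P")] == pytest.approx(table[("LIP", "P")])

    def test_duplicate_key_last_wins_with_warning(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("LIG C9 -0.1 2.0 0.3\nLIG C9 -0.2 2.1 0.4\n")
        with pytest.warns(UserWarning, match="duplicate"):
            table = read_params(path)
        assert table[("LIG", "C9")] == pytest.approx((-0.2, 2.1, 0.4))

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("LIG C9 -0.1 2.0\n")
        with pytest.raises(ParseError, match="5 columns"):
            read_params(path)


class TestSelection:
    def test_name_selects_phosphates(self, flat_bilayer):
        system, manifest = flat_bilayer
        idx = select_atoms(system, "name P")
        assert sorted(idx) == manifest["phosphate_indices"]

    def test_group_and_name_is_singleton(self, protein_ligand):
        system, _ = protein_ligand
        idx = select_atoms(system, "group ligand and name C9")
        assert len(idx) == 1
        assert system.names[idx[0]] == "C9"

    def test_not_group_on_pure_group_is_empty(self):
        system = MolecularSystem(
            [AtomRecord(1, "CA", "SER", 1, "A", "C", [0, 0, 0]),
             AtomRecord(2, "CA", "SER", 2, "A", "C", [1, 0, 0])],
            groups={"protein": [0, 1]})
        assert select_atoms(system, "not group protein").size == 0

    def test_set_algebra_and_idempotence(self, membrane_fixture):
        system, _ = membrane_fixture
        a = set(select_atoms(system, "group protein"))
        ab = set(select_atoms(system, "group protein and name CA"))
        assert ab <= a
        again = set(select_atoms(system, "group protein and name CA"))
        assert ab == again
        union = set(select_atoms(system, "group protein or name P"))
        assert a <= union

    def test_unknown_token_reports_position(self, flat_bilayer):
        system, _ = flat_bilayer
        with pytest.raises(SelectionError, match="position"):
            select_atoms(system, "name P and frobnicate")
        with pytest.raises(SelectionError):
            select_atoms(system, "resid notanumber")


class TestModelInvariants:
    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            AtomRecord(1, "CA", "SER", 1, "A", "C", [0, 0, 0],
                       lj_epsilon=-0.1)

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            AtomRecord(1, "CA", "SER", 1, "A", "C", [0, 0, np.inf])

    def test_duplicate_serials_rejected(self):
        atoms = [AtomRecord(1, "CA", "SER", 1, "A", "C", [0, 0, 0]),
                 AtomRecord(1, "CB", "SER", 1, "A", "C", [1, 0, 0])]
        with pytest.raises(ValueError, match="unique"):
            MolecularSystem(atoms)

    def test_times_must_increase(self):
        system = tiny_system()
        frames = np.stack([system.coords] * 2)
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(system=system, frames=frames, times=np.zeros(2))

    def test_combine_systems_offsets_groups(self, flat_bilayer,
                                            protein_ligand):
        bilayer, _ = flat_bilayer
        protein, _ = protein_ligand
        combined = combine_systems(bilayer, protein)
        assert combined.n_atoms == bilayer.n_atoms + protein.n_atoms
        lig = combined.groups["ligand"]
        assert all(i >= bilayer.n_atoms for i in lig)
        assert list(combined.names[lig]) == list(
            protein.names[protein.groups["ligand"]])
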