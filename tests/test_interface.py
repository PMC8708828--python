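import numpy as np
import pytest

from memscan.core_model import AtomRecord, MolecularSystem, Trajectory
from memscan.interface_contacts import (HbondCriteria, contact_series,
                                        contact_surface_area,
                                        contacting_residues, hydrogen_bonds)


def bead(serial, pos, name="C", res="SER", resid=None, element="C",
         rmin=1.8):
    return AtomRecord(serial, name, res, resid or serial, "A", element, pos,
                      charge=0.0, lj_rmin=rmin, lj_epsilon=0.3)


def plane_plus_sphere(gap=0.0):
    """3x3 bead plane (set M) with one sphere resting above it (set P)."""
    atoms = []
    k = 1
    for ix in range(3):
        for iy in range(3):
            atoms.append(bead(k, [3.0 * ix, 3.0 * iy, 0.0], res="LIP"))
            k += 1
    atoms.append(bead(k, [3.0, 3.0, 3.6 + gap], res="PRO"))
    system = MolecularSystem(atoms, groups={"m": list(range(9)), "p": [9]})
    return system


class TestContactArea:
    def test_far_sets_zero(self):
        system = plane_plus_sphere(gap=100.0)
        area = contact_surface_area(system.coords, system,
                                    system.groups["p"], system.groups["m"])
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_swap_symmetry(self):
        system = plane_plus_sphere()
        a = contact_surface_area(system.coords, system, system.groups["p"],
                                 system.groups["m"])
        b = contact_surface_area(system.coords, system, system.groups["m"],
                                 system.groups["p"])
        assert a == pytest.approx(b, rel=1e-12)
        assert a > 0

    def test_matches_independent_delta_sasa(self):
        # oracle: biotite Shrake-Rupley SASA differences
        import biotite.structure as struc

        system = plane_plus_sphere()
        radii = system.lj_rmin

        def bt_sasa(idx):
            idx = np.asarray(idx, int)
            arr = struc.AtomArray(len(idx))
            arr.coord = system.coords[idx].astype(np.float32)
            arr.atom_name = np.array(["C"] * len(idx))
            arr.res_name = np.array(["LIG"] * len(idx))
            arr.res_id = np.arange(1, len(idx) + 1)
            arr.chain_id = np.array(["A"] * len(idx))
            arr.element = np.array(["C"] * len(idx))
            return struc.sasa(arr, probe_radius=1.4, vdw_radii=radii[idx],
                              point_number=1000).sum()

        p, m = system.groups["p"], system.groups["m"]
        expected = bt_sasa(p) + bt_sasa(m) - bt_sasa(np.concatenate([p, m]))
        ours = contact_surface_area(system.coords, system, p, m,
                                    n_points=1000)
        assert ours == pytest.approx(expected, rel=0.02)

    def test_single_sided_is_half(self):
        system = plane_plus_sphere()
        both = contact_surface_area(system.coords, system,
                                    system.groups["p"], system.groups["m"])
        one = contact_surface_area(system.coords, system,
                                   system.groups["p"], system.groups["m"],
                                   single_sided=True)
        assert one == pytest.approx(both / 2.0, rel=1e-12)


def hbond_system(da_dist, angle_deg):
    """Donor D at origin, H on +x at 1.0 A, acceptor placed at distance
    ``da_dist`` from D so that the D-H...A angle equals ``angle_deg``."""
    # place A in the xy-plane: angle at H between H->D and H->A
    theta = np.deg2rad(180.0 - angle_deg)
    # find A by rotating from the D->H direction about z at H
    guess = np.array([1.0, 0.0, 0.0]) + (da_dist - 1.0) * np.array(
        [np.cos(theta), np.sin(theta), 0.0])
    # rescale so |D-A| = da_dist exactly while keeping the angle at H
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    vec = guess - h
    lo, hi = 0.0, 100.0
    for _ in range(80):
        mid = (lo + hi) / 2
        a = h + mid * vec / np.linalg.norm(vec)
        if np.linalg.norm(a - d) < da_dist:
            lo = mid
        else:
            hi = mid
    a = h + lo * vec / np.linalg.norm(vec)
    atoms = [bead(1, d, name="N", res="PRO", element="N"),
             bead(2, h, name="HN", res="PRO", element="H", rmin=0.8),
             bead(3, a, name="O", res="LIP", element="O")]
    return MolecularSystem(atoms)


def one_frame(system):
    return Trajectory(system=system, frames=system.coords[None],
                      times=np.zeros(1))


class TestHydrogenBonds:
    def test_close_linear_bond_counted(self):
        system = hbond_system(2.9, 170.0)
        _, mean = hydrogen_bonds(one_frame(system), [(0, 1)], [2])
        assert mean == 1.0

    def test_distant_pair_not_counted(self):
        system = hbond_system(6.0, 170.0)
        _, mean = hydrogen_bonds(one_frame(system), [(0, 1)], [2])
        assert mean == 0.0

    def test_bent_geometry_not_counted(self):
        system = hbond_system(2.9, 120.0)
        _, mean = hydrogen_bonds(one_frame(system), [(0, 1)], [2])
        assert mean == 0.0

    def test_constructed_k_bonds_average(self):
        # trajectory where exactly 1 geometric bond exists in every frame
        system = hbond_system(2.9, 170.0)
        frames = np.stack([system.coords] * 7)
        traj = Trajectory(system=system, frames=frames, times=np.arange(7.0))
        per_frame, mean = hydrogen_bonds(traj, [(0, 1)], [2])
        assert mean == 1.0
        assert all(b == [(0, 2)] for b in per_frame)

    def test_monotone_in_criteria(self):
        system = hbond_system(3.3, 155.0)
        traj = one_frame(system)
        loose = HbondCriteria(heavy_distance_max=3.5, angle_min=150.0)
        tight_d = HbondCriteria(heavy_distance_max=3.0, angle_min=150.0)
        tight_a = HbondCriteria(heavy_distance_max=3.5, angle_min=170.0)
        _, m0 = hydrogen_bonds(traj, [(0, 1)], [2], loose)
        _, m1 = hydrogen_bonds(traj, [(0, 1)], [2], tight_d)
        _, m2 = hydrogen_bonds(traj, [(0, 1)], [2], tight_a)
        assert m1 <= m0 and m2 <= m0

    def test_empty_donors_rejected(self):
        system = hbond_system(2.9, 170.0)
        with pytest.raises(ValueError):
            hydrogen_bonds(one_frame(system), [], [2])


class TestContactingResidues:
    def test_separated_sets_empty(self):
        system = plane_plus_sphere(gap=50.0)
        assert contacting_residues(system.coords, system,
                                   system.groups["p"],
                                   system.groups["m"]) == set()

    def test_zero_distance_empty(self):
        system = plane_plus_sphere()
        assert contacting_residues(system.coords, system,
                                   system.groups["p"], system.groups["m"],
                                   contact_distance=0.0) == set()

    def test_matches_brute_force_on_fixture(self, membrane_fixture):
        system, _ = membrane_fixture
        p = np.asarray(system.groups["protein"])
        m = np.asarray(system.groups["membrane"])
        got = contacting_residues(system.coords, system, p, m, 4.5)
        heavy = system.heavy_mask()
        expected = set()
        for i in p:
            if not heavy[i]:
                continue
            d = np.linalg.norm(system.coords[m[heavy[m]]]
                               - system.coords[i], axis=1)
            if np.any(d <= 4.5):
                expected.add(int(system.residue_ids[i]))
        assert got == expected
        assert expected  # the inserted helices do touch the leaflet

    def test_inserted_residues_are_helix_residues(self, membrane_fixture):
        system, manifest = membrane_fixture
        got = contacting_residues(system.coords, system,
                                  system.groups["protein"],
                                  system.groups["membrane"], 4.5)
        assert got <= set(manifest["protein"]["helix_residues"])

    def test_monotone_in_distance(self, membrane_fixture):
        system, _ = membrane_fixture
        p, m = system.groups["protein"], system.groups["membrane"]
        prev = set()
        for dist in (2.0, 4.5, 8.0, 15.0):
            cur = contacting_residues(system.coords, system, p, m, dist)
            assert prev <= cur
            prev = cur


def test_contact_series_reports_all_frames(membrane_fixture,
                                           static_trajectory):
    system, _ = membrane_fixture
    report = contact_series(static_trajectory, system.groups["protein"],
                            system.groups["membrane"], n_points=120)
    assert len(report.contact_area) == static_trajectory.n_frames
    assert report.summary()["contact_area"]["sd"] == pytest.approx(0.0,
                                                                   abs=1e-9)
    assert np.all(report.contact_area >= 0)
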