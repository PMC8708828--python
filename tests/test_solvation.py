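import numpy as np
import pytest

from memscan.core_model import AtomRecord, MolecularSystem, Trajectory
from memscan.nonbonded_energetics import interaction_energy
from memscan.solvation_binding import (MmpbsaConfig, PbGrid, mmpbsa_binding,
                                       pb_solve, sasa, solvation_terms,
                                       sphere_points)

BORN_2A = -(1389.35 / (2.0 * 2.0)) * (1.0 - 1.0 / 78.54)


def two_sphere_cap_area(r1, r2, d):
    """Closed-form accessible area of two overlapping spheres (both sides)."""
    full = 4.0 * np.pi * (r1 ** 2 + r2 ** 2)
    if d >= r1 + r2:
        return full
    # cap heights removed from each sphere
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    return full - 2.0 * np.pi * (r1 * h1 + r2 * h2)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        res = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4,
                   n_points=960)
        assert res.total == pytest.approx(4.0 * np.pi * 9.0, rel=0.005)

    def test_distant_atoms_additive(self):
        frame = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.6, 2.0])
        res = sasa(frame, radii, probe=1.4, n_points=960)
        expected = 4.0 * np.pi * ((1.6 + 1.4) ** 2 + (2.0 + 1.4) ** 2)
        assert res.total == pytest.approx(expected, rel=0.005)
        assert res.total == pytest.approx(res.per_atom.sum(), rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([1.6, 1.6])
        res = sasa(frame, radii, probe=1.4, n_points=4000)
        expected = two_sphere_cap_area(3.0, 3.0, d)
        assert res.total == pytest.approx(expected, rel=0.01)

    def test_adding_atoms_never_increases_existing_area(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            n = rng.integers(2, 7)
            frame = rng.uniform(-3, 3, (int(n), 3))
            radii = rng.uniform(1.2, 2.0, int(n))
            base = sasa(frame, radii, n_points=240)
            extra = rng.uniform(-3, 3, 3)
            grown = sasa(np.vstack([frame, extra]),
                         np.append(radii, 1.5), n_points=240)
            assert np.all(grown.per_atom[:int(n)] <= base.per_atom + 1e-9)

    def test_matches_independent_shrake_rupley(self):
        # cross-check against biotite's Shrake-Rupley on a random cluster
        import biotite.structure as struc

        rng = np.random.default_rng(19)
        n = 10
        frame = rng.uniform(-4, 4, (n, 3))
        radii = rng.uniform(1.3, 2.0, n)
        arr = struc.AtomArray(n)
        arr.coord = frame.astype(np.float32)
        arr.atom_name = np.array(["C"] * n)
        arr.res_name = np.array(["LIG"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        arr.element = np.array(["C"] * n)
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                         point_number=1000).sum()
        ours = sasa(frame, radii, probe=1.4, n_points=1000).total
        assert ours == pytest.approx(ref, rel=0.02)

    def test_point_set_is_deterministic_and_unit(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_points(960))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="92"):
            sasa(np.zeros((1, 3)), np.array([1.5]), n_points=50)


class TestPbSolve:
    def test_zero_charges_exactly_zero(self):
        g = pb_solve(np.zeros((1, 3)), np.array([0.0]), np.array([2.0]))
        assert g == 0.0

    def test_no_dielectric_contrast_zero(self):
        g = pb_solve(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                     PbGrid(spacing=0.8, eps_in=4.0, eps_out=4.0))
        assert g == 0.0

    def test_born_ion_within_5_percent(self):
        g = pb_solve(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                     PbGrid(spacing=0.4, eps_in=1.0, eps_out=78.54))
        assert g == pytest.approx(BORN_2A, rel=0.05)

    def test_grid_refinement_improves_born(self):
        errs = []
        for h in (0.8, 0.4):
            g = pb_solve(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                         PbGrid(spacing=h, eps_in=1.0, eps_out=78.54))
            errs.append(abs(g - BORN_2A))
        assert errs[1] < errs[0]

    def test_insufficient_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pb_solve(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                     PbGrid(spacing=0.8, extent=(8.0, 8.0, 8.0)))


def toy_complex():
    """5-atom parameterised complex: 4-atom receptor + 1-atom ligand."""
    coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0],
                       [1.5, 1.5, 1.5]])
    atoms = []
    charges = [0.3, -0.4, 0.2, -0.3, 0.5]
    for i in range(5):
        atoms.append(AtomRecord(i + 1, "C", "LIG", i + 1, "A", "C",
                                coords[i], charge=charges[i], lj_rmin=1.8,
                                lj_epsilon=0.3))
    return MolecularSystem(atoms, groups={"receptor": [0, 1, 2, 3],
                                          "ligand": [4]})


class TestSolvationTerms:
    def test_gamma_zero_gives_zero_nonpolar(self):
        system = toy_complex()
        config = MmpbsaConfig(eps_in=2.0, eps_out=2.0, gamma=0.0, beta=0.0)
        _, gnp = solvation_terms(system.coords, system, np.arange(5), config)
        assert gnp == 0.0

    def test_nonpolar_is_linear_in_sasa(self):
        system = toy_complex()
        config = MmpbsaConfig(eps_in=2.0, eps_out=2.0, gamma=0.0227,
                              beta=0.0, sasa_points=960)
        idx = np.arange(5)
        _, gnp = solvation_terms(system.coords, system, idx, config)
        area = sasa(system.coords, system.lj_rmin, probe=1.4,
                    n_points=960).total
        assert gnp == pytest.approx(0.0227 * area, rel=1e-12)

    def test_polar_composes_pb_solve(self):
        system = toy_complex()
        config = MmpbsaConfig(eps_in=1.0, eps_out=78.54, spacing=0.8)
        idx = np.arange(5)
        gp, _ = solvation_terms(system.coords, system, idx, config)
        direct = pb_solve(system.coords, system.charges, system.lj_rmin,
                          config.pb_grid())
        assert gp == pytest.approx(direct, rel=1e-9)


class TestMmpbsa:
    def test_solvation_disabled_reduces_to_uab(self):
        system = toy_complex()
        traj = Trajectory(system=system, frames=system.coords[None],
                          times=np.zeros(1))
        config = MmpbsaConfig(eps_in=2.0, eps_out=2.0, gamma=0.0, beta=0.0)
        report = mmpbsa_binding(traj, system.groups["receptor"],
                                system.groups["ligand"], config)
        uab = interaction_energy(system.coords, system,
                                 system.groups["receptor"],
                                 system.groups["ligand"])
        assert report.g_binding[0] == pytest.approx(uab.total, rel=1e-12)
        assert report.t_ds[0] == 0.0

    def test_toy_complex_matches_scripted_term_sum(self):
        # independent recomputation of all four terms with direct calls
        system = toy_complex()
        traj = Trajectory(system=system, frames=system.coords[None],
                          times=np.zeros(1))
        config = MmpbsaConfig(eps_in=1.0, eps_out=78.54, spacing=0.8,
                              gamma=0.0227, beta=0.1, sasa_points=240)
        report = mmpbsa_binding(traj, system.groups["receptor"],
                                system.groups["ligand"], config)
        rec = np.asarray(system.groups["receptor"])
        lig = np.asarray(system.groups["ligand"])
        both = np.concatenate([rec, lig])
        mm = interaction_energy(system.coords, system, rec, lig).total
        radii = system.lj_rmin
        span = (system.coords[both].max(axis=0)
                - system.coords[both].min(axis=0)
                + 2.0 * (radii[both].max() + 8.0))
        extent = tuple(float(s) for s in span)

        def entity_terms(idx):
            gp = pb_solve(system.coords[idx], system.charges[idx],
                          radii[idx], config.pb_grid(extent))
            area = sasa(system.coords[idx], radii[idx], 1.4, 240).total
            return gp, config.gamma * area + config.beta

        gp_c, gn_c = entity_terms(both)
        gp_r, gn_r = entity_terms(rec)
        gp_l, gn_l = entity_terms(lig)
        expected = mm + (gp_c - gp_r - gp_l) + (gn_c - gn_r - gn_l)
        assert report.g_binding[0] == pytest.approx(expected, rel=1e-9)
        # term-closure identity
        assert report.g_binding[0] == pytest.approx(
            report.mm_gas[0] + report.g_polar[0] + report.g_nonpolar[0]
            - report.t_ds[0], rel=1e-12)

    def test_identical_frames_sd_zero(self):
        system = toy_complex()
        traj = Trajectory(system=system,
                          frames=np.stack([system.coords] * 2),
                          times=np.arange(2.0))
        config = MmpbsaConfig(eps_in=2.0, eps_out=2.0, gamma=0.01)
        report = mmpbsa_binding(traj, system.groups["receptor"],
                                system.groups["ligand"], config)
        assert report.summary()["g_binding"]["sd"] == 0.0

    def test_rigid_motion_leaves_terms_unchanged(self):
        from scipy.spatial.transform import Rotation

        system = toy_complex()
        config = MmpbsaConfig(eps_in=1.0, eps_out=78.54, spacing=0.8,
                              gamma=0.0227)
        traj0 = Trajectory(system=system, frames=system.coords[None],
                           times=np.zeros(1))
        rot = Rotation.from_euler("xyz", [15, 25, 35],
                                  degrees=True).as_matrix()
        moved = system.coords @ rot.T + np.array([2.0, -1.0, 3.0])
        traj1 = Trajectory(system=system, frames=moved[None],
                           times=np.zeros(1))
        r0 = mmpbsa_binding(traj0, system.groups["receptor"],
                            system.groups["ligand"], config)
        r1 = mmpbsa_binding(traj1, system.groups["receptor"],
                            system.groups["ligand"], config)
        assert r1.mm_gas[0] == pytest.approx(r0.mm_gas[0], rel=1e-9)
        assert r1.g_nonpolar[0] == pytest.approx(r0.g_nonpolar[0], rel=0.02)
        # PB grid is axis-aligned; rotation changes discretisation slightly
        assert r1.g_polar[0] == pytest.approx(r0.g_polar[0], rel=0.15)

    def test_empty_or_overlapping_sets_rejected(self):
        system = toy_complex()
        traj = Trajectory(system=system, frames=system.coords[None],
                          times=np.zeros(1))
        with pytest.raises(ValueError):
            mmpbsa_binding(traj, [], [4])
        with pytest.raises(ValueError, match="disjoint"):
            mmpbsa_binding(traj, [0, 4], [4])
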