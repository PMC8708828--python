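import numpy as np
import pytest

from memscan.core_model import Trajectory
from memscan.synthetic_systems import (BilayerSpec, FluctuationSpec,
                                       make_bilayer,
                                       make_membrane_protein_fixture,
                                       make_protein_and_ligand,
                                       make_trajectory)


@pytest.fixture(scope="session")
def flat_bilayer():
    """Jitter-free bilayer: phosphate planes exactly at +/-19.5 A."""
    return make_bilayer(BilayerSpec(n_lipids_per_leaflet=16, jitter_sigma=0.0,
                                    seed=0))


@pytest.fixture(scope="session")
def jittered_bilayer():
    return make_bilayer(BilayerSpec(n_lipids_per_leaflet=128,
                                    jitter_sigma=1.0, seed=7))


@pytest.fixture(scope="session")
def protein_ligand():
    return make_protein_and_ligand(seed=3)


@pytest.fixture(scope="session")
def membrane_fixture():
    """Combined system: thickness 39, protein max heavy Z 10 A above MP2."""
    return make_membrane_protein_fixture(seed=0)


@pytest.fixture(scope="session")
def rpd25_fixture():
    """Thickness 40 / depth 10 construction: relative penetration 25%."""
    return make_membrane_protein_fixture(phosphate_separation=40.0,
                                         protein_max_z_above_mp2=10.0, seed=0)


@pytest.fixture()
def static_trajectory(membrane_fixture):
    system, _ = membrane_fixture
    n_res = len(system.residue_index_map())
    traj, _ = make_trajectory(system, FluctuationSpec(
        per_residue_sigma=[0.0] * n_res, n_frames=5, seed=0))
    return traj


def single_frame_traj(system):
    return Trajectory(system=system, frames=system.coords[None].copy(),
                      times=np.zeros(1))
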