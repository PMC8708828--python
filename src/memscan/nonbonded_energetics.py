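"""Pairwise 12-6 Lennard-Jones + Coulomb energies and the interaction-energy
partition between two atom sets.

The ligand-receptor interaction energy is the cross-set nonbonded sum

    Uab = U(A+B) - U(A) - U(B)

which, for a nonbonded-only model, reduces exactly to the sum over cross
pairs (intra-set terms cancel).  It is split into electrostatic (ELECT) and
van der Waals (VDW) components:

    vdw(r)   = eps_ab * [ (rmin_ab / r)^12 - 2 (rmin_ab / r)^6 ]
    elect(r) = k_e * q_a * q_b / r,      k_e = 1389.35 kJ mol^-1 A e^-2

with CHARMM-style combining: eps_ab = sqrt(eps_a eps_b) and
rmin_ab = rmin_a + rmin_b (per-atom values stored as half-Rmin).  The
relative permittivity is 1.  A plain distance cutoff can be applied (no
switching function); the default evaluates the full double sum.  The Fe2+
ion participates through these same terms only (unbonded scheme) -- there
is no element-specific code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import AtomRecord, MolecularSystem, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "EnergySeries",
    "pair_nonbonded",
    "interaction_energy",
    "energy_series",
]

# Coulomb constant in kJ/mol * angstrom / e^2 (vacuum permittivity).
COULOMB_CONSTANT = 1389.35


class ParameterError(ValueError):
    """An atom lacks the charge/LJ parameters the evaluation needs."""


@dataclass
class EnergyBreakdown:
    """Electrostatic + van der Waals components (kJ/mol); total is their sum."""

    elect: float
    vdw: float

    @property
    def total(self) -> float:
        return self.elect + self.vdw


@dataclass
class EnergySeries:
    """Per-frame energy components with mean and sample SD per component."""

    times: np.ndarray
    elect: np.ndarray
    vdw: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.elect + self.vdw

    def _stat(self, x: np.ndarray) -> Tuple[float, float]:
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return float(np.mean(x)), sd

    def summary(self) -> dict:
        out = {}
        for key, series in (("elect", self.elect), ("vdw", self.vdw),
                            ("total", self.total)):
            mean, sd = self._stat(series)
            out[key] = {"mean": mean, "sd": sd}
        return out


def _require_params(atom: AtomRecord) -> None:
    if atom.charge is None or atom.lj_rmin is None or atom.lj_epsilon is None:
        raise ParameterError(
            f"atom serial {atom.serial} ({atom.residue_name}/{atom.name}) "
            "is missing charge or LJ parameters")


def pair_nonbonded(atom_a: AtomRecord, atom_b: AtomRecord,
                   r: float) -> EnergyBreakdown:
    """Nonbonded energy of a single atom pair at separation ``r`` (angstrom)."""
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    _require_params(atom_a)
    _require_params(atom_b)
    eps = np.sqrt(atom_a.lj_epsilon * atom_b.lj_epsilon)
    rmin = atom_a.lj_rmin + atom_b.lj_rmin
    q = (rmin / r) ** 6
    vdw = eps * (q * q - 2.0 * q)
    elect = COULOMB_CONSTANT * atom_a.charge * atom_b.charge / r
    return EnergyBreakdown(elect=float(elect), vdw=float(vdw))


def _check_params_array(system: MolecularSystem, idx: np.ndarray) -> None:
    bad = idx[np.isnan(system.charges[idx]) | np.isnan(system.lj_rmin[idx])
              | np.isnan(system.lj_epsilon[idx])]
    if bad.size:
        i = int(bad[0])
        raise ParameterError(
            f"atom serial {int(system.serials[i])} "
            f"({system.residue_names[i]}/{system.names[i]}) "
            "is missing charge or LJ parameters")


def interaction_energy(frame: np.ndarray, system: MolecularSystem,
                       set_a, set_b,
                       cutoff: Optional[float] = None) -> EnergyBreakdown:
    """Cross-set nonbonded energy between two disjoint atom sets.

    ``cutoff=None`` evaluates every cross pair; ``cutoff=c`` drops pairs with
    r > c (plain truncation, no switching).
    """
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("both atom sets must be nonempty")
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("atom sets must be disjoint")
    _check_params_array(system, set_a)
    _check_params_array(system, set_b)
    r = cdist(frame[set_a], frame[set_b])
    if np.any(r == 0.0):
        ia, ib = np.argwhere(r == 0.0)[0]
        raise ValueError(
            f"zero distance between atoms serial "
            f"{int(system.serials[set_a[ia]])} and "
            f"{int(system.serials[set_b[ib]])}")
    mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)
    qa = system.charges[set_a][:, None]
    qb = system.charges[set_b][None, :]
    eps = np.sqrt(system.lj_epsilon[set_a][:, None]
                  * system.lj_epsilon[set_b][None, :])
    rmin = system.lj_rmin[set_a][:, None] + system.lj_rmin[set_b][None, :]
    with np.errstate(over="raise"):
        q6 = (rmin / r) ** 6
        vdw = eps * (q6 * q6 - 2.0 * q6)
        elect = COULOMB_CONSTANT * qa * qb / r
    return EnergyBreakdown(elect=float(np.sum(elect[mask])),
                           vdw=float(np.sum(vdw[mask])))


def energy_series(traj: Trajectory, set_a, set_b,
                  cutoff: Optional[float] = None,
                  stride: int = 1) -> EnergySeries:
    """Per-frame cross-set energies over a trajectory (optionally strided)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(0, traj.n_frames, stride)
    elect = np.empty(len(idx))
    vdw = np.empty(len(idx))
    for k, i in enumerate(idx):
        try:
            e = interaction_energy(traj.frames[i], traj.system, set_a, set_b,
                                   cutoff)
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        elect[k], vdw[k] = e.elect, e.vdw
    return EnergySeries(times=traj.times[idx].copy(), elect=elect, vdw=vdw)
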