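"""Protein-membrane interface analysis: buried contact surface area,
geometric hydrogen bonds and contacting-residue lists.

Contact area between atom sets P and M is the buried interface area

    area = SASA(P) + SASA(M) - SASA(P u M)

summed over both sides of the interface (the single-sided value, half of
this, is available via ``single_sided=True``).

A hydrogen bond D-H...A is counted when the heavy-atom donor-acceptor
distance is at most ``heavy_distance_max`` (default 3.5 angstrom) and the
D-H...A angle is at least ``angle_min`` (default 150 degrees) -- standard
MD-analysis practice; both cutoffs are configurable since geometric
criteria are a convention, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core_model import MolecularSystem, Trajectory
from .solvation_binding import sasa

__all__ = [
    "HbondCriteria",
    "ContactReport",
    "contact_surface_area",
    "hydrogen_bonds",
    "contacting_residues",
    "contact_series",
]


@dataclass
class HbondCriteria:
    heavy_distance_max: float = 3.5
    angle_min: float = 150.0

    def __post_init__(self) -> None:
        if self.heavy_distance_max <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.angle_min <= 180):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class ContactReport:
    times: np.ndarray
    contact_area: np.ndarray
    hbond_counts: np.ndarray
    contacting: List[Set[int]]

    def summary(self) -> dict:
        def stat(x):
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            return {"mean": float(np.mean(x)), "sd": sd}

        return {"contact_area": stat(self.contact_area),
                "hbond_count": stat(self.hbond_counts)}


def contact_surface_area(frame: np.ndarray, system: MolecularSystem,
                         set_p, set_m, probe: float = 1.4,
                         n_points: int = 240,
                         single_sided: bool = False) -> float:
    """Buried interface area between two disjoint atom sets (angstrom^2)."""
    set_p = np.asarray(set_p, int)
    set_m = np.asarray(set_m, int)
    if np.intersect1d(set_p, set_m).size:
        raise ValueError("atom sets must be disjoint")
    radii = system.lj_rmin
    if np.any(~np.isfinite(radii[np.concatenate([set_p, set_m])])):
        raise ValueError("all atoms need radii (lj_rmin) for contact area")
    a_p = sasa(frame[set_p], radii[set_p], probe, n_points).total
    a_m = sasa(frame[set_m], radii[set_m], probe, n_points).total
    union = np.concatenate([set_p, set_m])
    a_u = sasa(frame[union], radii[union], probe, n_points).total
    buried = a_p + a_m - a_u
    return float(buried / 2.0 if single_sided else buried)


def _frame_hbonds(frame: np.ndarray, donors, acceptors,
                  criteria: HbondCriteria) -> List[Tuple[int, int]]:
    bonds = []
    cos_min = np.cos(np.deg2rad(180.0 - criteria.angle_min))
    for d, h in donors:
        da = frame[np.asarray(acceptors)] - frame[d]
        dist = np.linalg.norm(da, axis=1)
        dh = frame[h] - frame[d]
        ha = frame[np.asarray(acceptors)] - frame[h]
        for a, r, vec in zip(acceptors, dist, ha):
            if a == d or a == h or r > criteria.heavy_distance_max:
                continue
            nh = np.linalg.norm(dh)
            na = np.linalg.norm(vec)
            if nh == 0 or na == 0:
                continue
            # angle D-H...A at the hydrogen
            cos_angle = float(np.dot(-dh, vec) / (nh * na))
            angle = np.rad2deg(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
            if angle >= criteria.angle_min:
                bonds.append((int(d), int(a)))
    return bonds


def hydrogen_bonds(traj: Trajectory, donors: Sequence[Tuple[int, int]],
                   acceptors, criteria: HbondCriteria = HbondCriteria()
                   ) -> Tuple[List[List[Tuple[int, int]]], float]:
    """Per-frame hydrogen-bond lists and the mean count over frames.

    ``donors`` are (heavy donor, attached hydrogen) index pairs; ``acceptors``
    heavy-atom indices.  Returns ``(per_frame_bond_lists, mean_count)``.
    """
    donors = list(donors)
    acceptors = list(int(a) for a in np.asarray(acceptors, int))
    if not donors or not acceptors:
        raise ValueError("need at least one donor pair and one acceptor")
    per_frame = [_frame_hbonds(f, donors, acceptors, criteria)
                 for f in traj.frames]
    mean = float(np.mean([len(b) for b in per_frame]))
    return per_frame, mean


def contacting_residues(frame: np.ndarray, system: MolecularSystem,
                        set_p, set_m,
                        contact_distance: float = 4.5) -> Set[int]:
    """Residue ids of P with any heavy atom within ``contact_distance`` of
    any heavy atom of M (default 4.5 angstrom)."""
    if contact_distance < 0:
        raise ValueError("contact distance must be >= 0")
    set_p = np.asarray(set_p, int)
    set_m = np.asarray(set_m, int)
    heavy = system.heavy_mask()
    p = set_p[heavy[set_p]]
    m = set_m[heavy[set_m]]
    if p.size == 0 or m.size == 0 or contact_distance == 0:
        return set()
    tree = cKDTree(frame[m])
    near = tree.query_ball_point(frame[p], contact_distance)
    return {int(system.residue_ids[i])
            for i, hits in zip(p, near) if len(hits)}


def contact_series(traj: Trajectory, set_p, set_m,
                   donors: Sequence[Tuple[int, int]] = (),
                   acceptors=(),
                   criteria: HbondCriteria = HbondCriteria(),
                   probe: float = 1.4, n_points: int = 240,
                   contact_distance: float = 4.5) -> ContactReport:
    """Per-frame contact area, hydrogen-bond counts and contacting residues."""
    areas = np.empty(traj.n_frames)
    contacting: List[Set[int]] = []
    for i, frame in enumerate(traj.frames):
        areas[i] = contact_surface_area(frame, traj.system, set_p, set_m,
                                        probe, n_points)
        contacting.append(contacting_residues(frame, traj.system, set_p,
                                              set_m, contact_distance))
    if len(donors) and len(list(acceptors)):
        per_frame, _ = hydrogen_bonds(traj, donors, acceptors, criteria)
        counts = np.array([len(b) for b in per_frame], dtype=float)
    else:
        counts = np.zeros(traj.n_frames)
    return ContactReport(times=traj.times.copy(), contact_area=areas,
                         hbond_counts=counts, contacting=contacting)
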