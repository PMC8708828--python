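"""Rigid-body insertion of a protein into an implicit hydrophobic slab.

The membrane is an implicit slab of half-width ``half_width`` centred on
z = 0.  The transfer free energy of a rigid pose is an ASA-weighted sum

    dG_transfer(pose) = sum_atoms sigma(residue) * ASA_atom * f(z_atom)

where sigma is a residue-level transfer coefficient (kJ mol^-1 A^-2,
negative = hydrophobic, favours burial), ASA_atom is the solvent-accessible
area of the atom in the isolated protein (pose independent, computed once),
and f(z) is the slab indicator: 1 in the core (|z| <= half_width -
smoothing), 0 outside the slab (|z| >= half_width), linear in between.

``optimize_insertion`` scans an exhaustive depth x tilt x azimuth grid
(default depth step 0.2 angstrom) and reports the global minimum, the angle
between the protein's first principal axis of inertia and the slab plane,
and the contacting / outside residue partition.  This is a deliberately
simplified positioning model in the spirit of implicit-slab orientation
methods, not a full solvation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np

from .core_model import MolecularSystem
from .solvation_binding import sasa

__all__ = [
    "DEFAULT_TRANSFER_SCALE",
    "SlabModel",
    "InsertionResult",
    "slab_fraction",
    "transfer_energy",
    "optimize_insertion",
]

# Residue-level transfer coefficients, kJ mol^-1 A^-2, derived from the
# Kyte-Doolittle hydropathy index scaled by -0.0125 (so LEU at +3.8 gives
# sigma = -0.0475: burying hydrophobic area is favourable).  Fixture bead
# residues reuse the scale of their namesakes.
_KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
DEFAULT_TRANSFER_SCALE: Dict[str, float] = {
    res: -0.0125 * kd for res, kd in _KD.items()
}


@dataclass
class SlabModel:
    """Implicit hydrophobic slab: geometry plus the transfer scale."""

    half_width: float = 15.0
    interface_smoothing: float = 3.0
    sigma: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFER_SCALE))

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.interface_smoothing < 0:
            raise ValueError("interface_smoothing must be >= 0")


@dataclass
class InsertionResult:
    angle: float  # degrees, first principal inertia axis vs slab plane
    depth: float  # angstrom below the upper slab face (see transfer_energy)
    tilt: float
    azimuth: float
    dg_transfer: float  # kJ/mol
    contacting_residues: Set[int]
    outside_residues: Set[int]


def slab_fraction(z: np.ndarray, slab: SlabModel) -> np.ndarray:
    """Membrane-exposure weight f(z): 1 in the core, 0 outside, linear ramp."""
    az = np.abs(np.asarray(z, float))
    if slab.interface_smoothing == 0:
        return (az <= slab.half_width).astype(float)
    return np.clip((slab.half_width - az) / slab.interface_smoothing,
                   0.0, 1.0)


def _sigma_per_atom(system: MolecularSystem, idx: np.ndarray,
                    slab: SlabModel) -> np.ndarray:
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        res = str(system.residue_names[i])
        if res not in slab.sigma:
            raise KeyError(f"no transfer coefficient for residue type {res!r}")
        out[k] = slab.sigma[res]
    return out


def _rot(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Pose rotation: azimuth about z, then tilt about x."""
    ca, sa = np.cos(np.deg2rad(azimuth_deg)), np.sin(np.deg2rad(azimuth_deg))
    ct, st = np.cos(np.deg2rad(tilt_deg)), np.sin(np.deg2rad(tilt_deg))
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    return rx @ rz


def pose_coords(frame: np.ndarray, idx: np.ndarray, slab: SlabModel,
                pose: Tuple[float, float, float]) -> np.ndarray:
    """Protein coordinates rigidly placed at ``pose = (depth, tilt, azimuth)``.

    The protein is rotated about its geometric centre, then translated so
    that its lowest atom sits ``depth`` angstrom below the upper slab face
    (depth 0: touching the face from outside, deeper = more inserted).
    """
    depth, tilt, azimuth = pose
    if not all(np.isfinite([depth, tilt, azimuth])):
        raise ValueError("pose must be finite")
    coords = frame[idx]
    center = coords.mean(axis=0)
    rot = _rot(tilt, azimuth)
    out = (coords - center) @ rot.T
    z_min = out[:, 2].min()
    out[:, 2] += slab.half_width - depth - z_min
    return out


def transfer_energy(frame: np.ndarray, system: MolecularSystem,
                    slab: SlabModel, pose: Tuple[float, float, float],
                    protein=None, asa: Optional[np.ndarray] = None,
                    probe: float = 1.4, n_points: int = 240) -> float:
    """dG of transferring the rigidly posed protein into the slab, kJ/mol."""
    idx = (np.asarray(protein, int) if protein is not None
           else np.arange(system.n_atoms))
    if asa is None:
        asa = sasa(frame[idx], system.lj_rmin[idx], probe, n_points).per_atom
    sigma = _sigma_per_atom(system, idx, slab)
    coords = pose_coords(frame, idx, slab, pose)
    f = slab_fraction(coords[:, 2], slab)
    return float(np.sum(sigma * asa * f))


def _principal_axis_angle(coords: np.ndarray) -> float:
    """Angle (deg, in [0, 90]) between the first principal axis of inertia
    (unit masses) and the slab XY plane."""
    centered = coords - coords.mean(axis=0)
    # principal axis of the gyration tensor = largest-variance direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    sin_angle = abs(axis[2]) / np.linalg.norm(axis)
    return float(np.rad2deg(np.arcsin(np.clip(sin_angle, 0.0, 1.0))))


def optimize_insertion(frame: np.ndarray, system: MolecularSystem,
                       slab: SlabModel, depth_step: float = 0.2,
                       tilt_step: float = 2.0, azimuth_step: float = 30.0,
                       depth_max: Optional[float] = None,
                       tilt_max: float = 90.0,
                       protein=None, probe: float = 1.4,
                       n_points: int = 240) -> InsertionResult:
    """Exhaustive grid search over depth x tilt x azimuth poses.

    The non-inserted pose (dG = 0) is always part of the search, so the
    reported optimum is <= 0 whenever any negative-energy pose exists.
    Ties keep the first pose in scan order (tilt, then azimuth, then depth),
    i.e. the smallest azimuth among degenerate mirror poses.
    """
    if depth_step <= 0 or tilt_step <= 0 or azimuth_step <= 0:
        raise ValueError("grid steps must be > 0")
    idx = (np.asarray(protein, int) if protein is not None
           else np.arange(system.n_atoms))
    asa = sasa(frame[idx], system.lj_rmin[idx], probe, n_points).per_atom
    sigma = _sigma_per_atom(system, idx, slab)
    coords0 = frame[idx] - frame[idx].mean(axis=0)
    z_span = coords0[:, 2].max() - coords0[:, 2].min()
    if depth_max is None:
        depth_max = 2.0 * slab.half_width + z_span
    depths = np.arange(0.0, depth_max + 1e-9, depth_step)
    tilts = np.arange(0.0, tilt_max + 1e-9, tilt_step)
    azimuths = np.arange(0.0, 360.0 - 1e-9, azimuth_step)
    if depths.size == 0 or tilts.size == 0 or azimuths.size == 0:
        raise ValueError("empty pose grid")

    best = (0.0, (0.0, 0.0, 0.0))  # the non-inserted reference pose
    for tilt in tilts:
        for azimuth in azimuths:
            rot = _rot(tilt, azimuth)
            rc = coords0 @ rot.T
            z0 = rc[:, 2] - rc[:, 2].min()  # offsets above the lowest atom
            for depth in depths:
                z = z0 + slab.half_width - depth
                f = slab_fraction(z, slab)
                dg = float(np.sum(sigma * asa * f))
                if dg < best[0] - 1e-12:
                    best = (dg, (depth, tilt, azimuth))
    dg, (depth, tilt, azimuth) = best
    posed = pose_coords(frame, idx, slab, (depth, tilt, azimuth))
    f = slab_fraction(posed[:, 2], slab)
    resids = system.residue_ids[idx]
    contacting = {int(r) for r, w in zip(resids, f) if w > 0}
    outside = {int(r) for r in resids} - contacting
    return InsertionResult(
        angle=_principal_axis_angle(posed), depth=float(depth),
        tilt=float(tilt), azimuth=float(azimuth), dg_transfer=dg,
        contacting_residues=contacting, outside_residues=outside)
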