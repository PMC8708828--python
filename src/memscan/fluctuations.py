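"""Rigid superposition (Kabsch), RMSD series, per-residue RMSF and the
membrane-vs-solvent fluctuation contrast.

RMSF is computed after superposing every frame onto an iteratively refined
mean structure (two passes: fit to the initial mean, recompute the mean,
re-fit), so that global rigid motion does not inflate the fluctuations.
The per-residue value is the unweighted mean of the residue's per-atom
RMSF values.

The fluctuation contrast for residue i is

    delta_rmsf_i = <RMSF_i>_membrane - <RMSF_i>_solvent

evaluated on the residue intersection of the two profiles; a negative value
means the membrane rigidifies that region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core_model import MolecularSystem, Trajectory

__all__ = [
    "FluctuationProfile",
    "DeltaRmsfProfile",
    "superpose_kabsch",
    "rmsd_series",
    "rmsf_profile",
    "delta_rmsf",
]


@dataclass
class FluctuationProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # angstrom, >= 0

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be >= 0")

    def as_dict(self) -> Dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.residue_ids, self.rmsf)}


@dataclass
class DeltaRmsfProfile:
    residue_ids: np.ndarray
    delta_rmsf: np.ndarray  # signed, angstrom
    missing_in_memb: Tuple[int, ...] = ()
    missing_in_sol: Tuple[int, ...] = ()


def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray,
                     fit_set: Optional[np.ndarray] = None
                     ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of mobile onto reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over
    ``fit_set`` (all atoms when None).  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    idx = np.arange(len(mobile)) if fit_set is None else np.asarray(fit_set, int)
    if idx.size < 3:
        raise ValueError("fit set needs at least 3 atoms")
    x = mobile[idx]
    y = reference[idx]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # Degeneracy check: collinear points leave a rotation dof undetermined.
    s = np.linalg.svd(x0, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit set")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def _fit_frame(frame: np.ndarray, reference: np.ndarray,
               fit_set: Optional[np.ndarray]) -> np.ndarray:
    rot, trans, _ = superpose_kabsch(frame, reference, fit_set)
    return frame @ rot.T + trans


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                fit_set: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame RMSD over the fit set after Kabsch superposition."""
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        _, _, out[i] = superpose_kabsch(frame, reference, fit_set)
    return out


def rmsf_profile(traj: Trajectory, fit_set: Optional[np.ndarray] = None,
                 report_set: Optional[np.ndarray] = None) -> FluctuationProfile:
    """Per-residue RMSF about the iteratively refined mean structure.

    ``fit_set`` (default: all atoms of ``report_set``) is used for the
    superposition; ``report_set`` (default: all atoms) selects the atoms whose
    residues are reported.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    report = (np.arange(traj.system.n_atoms) if report_set is None
              else np.asarray(report_set, int))
    fit = report if fit_set is None else np.asarray(fit_set, int)

    fitted = np.array([_fit_frame(f, traj.frames[0], fit) for f in traj.frames])
    mean = fitted.mean(axis=0)
    fitted = np.array([_fit_frame(f, mean, fit) for f in traj.frames])
    mean = fitted.mean(axis=0)

    dev2 = np.mean(np.sum((fitted - mean[None]) ** 2, axis=2), axis=0)
    atom_rmsf = np.sqrt(dev2)

    resids = traj.system.residue_ids
    out_ids = []
    out_rmsf = []
    seen = {}
    for i in report:
        seen.setdefault(int(resids[i]), []).append(atom_rmsf[i])
    for rid, vals in seen.items():
        out_ids.append(rid)
        out_rmsf.append(float(np.mean(vals)))
    return FluctuationProfile(residue_ids=np.asarray(out_ids),
                              rmsf=np.asarray(out_rmsf))


def delta_rmsf(memb: FluctuationProfile, sol: FluctuationProfile
               ) -> DeltaRmsfProfile:
    """Membrane-minus-solvent RMSF difference on the residue intersection.

    Residues present in only one input are reported as missing, never as
    zero differences.
    """
    m = memb.as_dict()
    s = sol.as_dict()
    common = sorted(set(m) & set(s))
    if not common:
        raise ValueError("profiles share no residues")
    delta = np.array([m[r] - s[r] for r in common])
    return DeltaRmsfProfile(
        residue_ids=np.asarray(common, dtype=int),
        delta_rmsf=delta,
        missing_in_memb=tuple(sorted(set(s) - set(m))),
        missing_in_sol=tuple(sorted(set(m) - set(s))),
    )
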