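"""Membrane penetration geometry: leaflet assignment, thickness, depth, RPD.

The bilayer phosphates, projected on the membrane normal (Z), are split into
two sets: MP2 is the leaflet on the side where the protein is inserted, MP1
the opposite leaflet.  Per frame:

* thickness = <Z(MP1)> - <Z(MP2)>
* depth     = Max(Z_protein, heavy atoms) - <Z(MP2)>
* RPD       = 100 * depth / thickness   (relative penetration depth, %)

Frames are canonicalised so that MP1 is the upper leaflet (mean Z(MP1) >
mean Z(MP2)); if the protein sits on the upper side the whole frame's Z is
mirrored first, which leaves all three metrics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core_model import MolecularSystem, Trajectory

__all__ = [
    "BilayerModel",
    "PenetrationProfile",
    "assign_leaflets",
    "penetration_metrics",
    "penetration_series",
]


class DegenerateBilayerError(ValueError):
    """All phosphates fell on one side of their joint Z mean."""


@dataclass
class BilayerModel:
    """Leaflet partition of the phosphate atoms for one frame.

    ``flip_z`` records whether the frame had to be Z-mirrored to put the
    protein-side leaflet (MP2) at the bottom.
    """

    mp1: np.ndarray  # far leaflet phosphate indices
    mp2: np.ndarray  # protein-side leaflet phosphate indices
    normal_axis: str = "z"
    flip_z: bool = False

    def __post_init__(self) -> None:
        self.mp1 = np.asarray(self.mp1, dtype=int)
        self.mp2 = np.asarray(self.mp2, dtype=int)
        if self.mp1.size == 0 or self.mp2.size == 0:
            raise DegenerateBilayerError("both leaflets must be nonempty")
        if np.intersect1d(self.mp1, self.mp2).size:
            raise ValueError("MP1 and MP2 must be disjoint")

    @property
    def n_i(self) -> int:
        return len(self.mp1)

    @property
    def n_j(self) -> int:
        return len(self.mp2)


@dataclass
class PenetrationProfile:
    """Per-frame thickness/depth/RPD series with their means and sample SDs."""

    times: np.ndarray
    thickness: np.ndarray
    depth: np.ndarray
    rpd: np.ndarray

    def _stat(self, x: np.ndarray) -> Tuple[float, float]:
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return float(np.mean(x)), sd

    @property
    def thickness_mean_sd(self) -> Tuple[float, float]:
        return self._stat(self.thickness)

    @property
    def depth_mean_sd(self) -> Tuple[float, float]:
        return self._stat(self.depth)

    @property
    def rpd_mean_sd(self) -> Tuple[float, float]:
        return self._stat(self.rpd)

    def summary(self) -> dict:
        out = {}
        for key in ("thickness", "depth", "rpd"):
            mean, sd = self._stat(getattr(self, key))
            out[key] = {"mean": mean, "sd": sd}
        return out


def _canonical_frame(frame: np.ndarray, phosphates: np.ndarray,
                     protein: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Mirror Z if the protein centre is on the upper phosphate side."""
    z = frame[phosphates, 2]
    z_mean = z.mean()
    protein_center_z = frame[protein, 2].mean()
    if protein_center_z > z_mean:
        out = frame.copy()
        out[:, 2] = 2.0 * z_mean - out[:, 2]
        return out, True
    return frame, False


def assign_leaflets(frame: np.ndarray, phosphates, protein) -> BilayerModel:
    """Partition phosphates into MP1/MP2 by sign of Z - <Z(phosphates)>.

    MP2 is the leaflet whose mean Z is nearer the protein centre of geometry.
    The model is canonical: after any recorded Z-flip, mean Z(MP1) > mean
    Z(MP2), i.e. the protein approaches from below.
    """
    phosphates = np.asarray(phosphates, dtype=int)
    protein = np.asarray(protein, dtype=int)
    if phosphates.size < 4:
        raise ValueError("need at least 4 phosphates (2 per leaflet)")
    if protein.size == 0:
        raise ValueError("empty protein selection")
    work, flipped = _canonical_frame(frame, phosphates, protein)
    z = work[phosphates, 2]
    z_mean = z.mean()
    upper = phosphates[z > z_mean]
    lower = phosphates[z <= z_mean]
    if upper.size < 2 or lower.size < 2:
        raise DegenerateBilayerError(
            f"degenerate bilayer: {upper.size} phosphates above / "
            f"{lower.size} below their joint Z mean")
    # After canonicalisation the protein is below, so MP2 = lower leaflet.
    return BilayerModel(mp1=upper, mp2=lower, flip_z=flipped)


def penetration_metrics(frame: np.ndarray, bilayer: BilayerModel,
                        protein, heavy_mask: Optional[np.ndarray] = None
                        ) -> Tuple[float, float, float]:
    """Thickness, depth and RPD for one frame under a leaflet model.

    Hydrogen atoms are excluded from the protein Z maximum when a
    ``heavy_mask`` (per-atom boolean, True = heavy) is supplied.
    """
    protein = np.asarray(protein, dtype=int)
    if protein.size == 0:
        raise ValueError("empty protein selection")
    work = frame
    if bilayer.flip_z:
        all_p = np.concatenate([bilayer.mp1, bilayer.mp2])
        z_mean = frame[all_p, 2].mean()
        work = frame.copy()
        work[:, 2] = 2.0 * z_mean - work[:, 2]
    z_mp1 = work[bilayer.mp1, 2].mean()
    z_mp2 = work[bilayer.mp2, 2].mean()
    thickness = z_mp1 - z_mp2
    if thickness <= 0:
        raise RuntimeError(
            "internal error: canonical orientation gave non-positive thickness")
    prot = protein
    if heavy_mask is not None:
        prot = protein[np.asarray(heavy_mask, bool)[protein]]
        if prot.size == 0:
            raise ValueError("protein selection has no heavy atoms")
    depth = work[prot, 2].max() - z_mp2
    rpd = 100.0 * depth / thickness
    return float(thickness), float(depth), float(rpd)


def penetration_series(traj: Trajectory, phosphates, protein) -> PenetrationProfile:
    """Per-frame penetration metrics; leaflets reassigned every frame."""
    phosphates = np.asarray(phosphates, dtype=int)
    protein = np.asarray(protein, dtype=int)
    heavy = traj.system.heavy_mask()
    thickness = np.empty(traj.n_frames)
    depth = np.empty(traj.n_frames)
    rpd = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        try:
            model = assign_leaflets(frame, phosphates, protein)
            thickness[i], depth[i], rpd[i] = penetration_metrics(
                frame, model, protein, heavy_mask=heavy)
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return PenetrationProfile(times=traj.times.copy(), thickness=thickness,
                              depth=depth, rpd=rpd)
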