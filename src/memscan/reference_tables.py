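"""Published reference values for the citrus CCD4-carotenoid-membrane study
system, bundled as worked-example inputs.

These are transcriptions of reported all-atom MD results for the three
*Citrus clementina* CCD4 paralogues (CCD4a, CCD4b, CCD4c):

* ``TRANSFER_TABLE`` -- implicit-slab insertion results per protein: tilt
  angle of the first principal inertia axis vs the membrane plane (deg),
  penetration depth (angstrom) and dG_transfer (kJ/mol).
* ``UAB_TABLE`` -- ligand-receptor interaction energies, electrostatic and
  van der Waals components with their reported totals (kJ/mol, mean and SD
  over trajectories).
* ``SITE_TABLE`` -- mean distances (angstrom) from the labelled carotenoid
  carbons (C7, C8, C9, C10, C15, C15' = C15P) to the catalytic Fe2+, plus
  the MM/PBSA binding free energy (kJ/mol).  ``RRX*`` is the
  beta-cryptoxanthin complex of CCD4b re-sampled on a 1 microsecond
  trajectory.

Ligand codes: 3ON 3-hydroxy-8'-apocarotenol, ACR alpha-carotene, BCR
beta-carotene, LYC lycopene, LUT lutein, RRX beta-cryptoxanthin, ZEX
zeaxanthin.

The worked-example report recomputes derived quantities (component sums,
column means, minima, cleavage calls, rankings) from these inputs and checks
them against the reported derived values.
"""

from __future__ import annotations

from typing import Dict, Tuple

__all__ = ["TRANSFER_TABLE", "UAB_TABLE", "SITE_TABLE",
           "REPORTED_TRANSFER_MEAN"]

# protein -> (angle_deg, depth_A, dg_transfer_kJ_mol)
TRANSFER_TABLE: Dict[str, Tuple[float, float, float]] = {
    "CCD4a": (32.0, 7.0, -64.4),
    "CCD4b": (39.0, 5.8, -61.5),
    "CCD4c": (28.0, 5.2, -48.5),
}

# Reported average of the dG_transfer column above.
REPORTED_TRANSFER_MEAN = -58.1

# (receptor, ligand) -> {"elect": (mean, sd), "vdw": (mean, sd),
#                        "total": (mean, sd)}   [kJ/mol]
UAB_TABLE: Dict[Tuple[str, str], Dict[str, Tuple[float, float]]] = {
    ("CCD4a", "3ON"): {"elect": (-116.50, 23.93), "vdw": (-274.37, 16.58),
                       "total": (-390.87, 23.61)},
    ("CCD4a", "ACR"): {"elect": (-33.11, 10.16), "vdw": (-344.21, 18.75),
                       "total": (-377.32, 22.07)},
    ("CCD4a", "BCR"): {"elect": (-21.03, 8.75), "vdw": (-344.23, 17.66),
                       "total": (-365.26, 19.51)},
    ("CCD4a", "LYC"): {"elect": (-32.66, 10.96), "vdw": (-351.83, 15.51),
                       "total": (-384.49, 18.94)},
    ("CCD4a", "LUT"): {"elect": (-110.95, 21.48), "vdw": (-342.63, 17.54),
                       "total": (-453.58, 23.83)},
    ("CCD4a", "RRX"): {"elect": (-77.24, 16.85), "vdw": (-333.07, 17.81),
                       "total": (-410.30, 21.77)},
    ("CCD4a", "ZEX"): {"elect": (-135.94, 25.19), "vdw": (-316.85, 18.62),
                       "total": (-452.79, 26.42)},
    ("CCD4b", "3ON"): {"elect": (-124.99, 27.10), "vdw": (-271.27, 18.53),
                       "total": (-396.27, 24.13)},
    ("CCD4b", "ACR"): {"elect": (-33.41, 10.80), "vdw": (-351.57, 16.37),
                       "total": (-384.97, 21.24)},
    ("CCD4b", "BCR"): {"elect": (-31.76, 10.65), "vdw": (-342.07, 14.83),
                       "total": (-373.83, 18.16)},
    ("CCD4b", "LYC"): {"elect": (-32.05, 10.86), "vdw": (-367.96, 15.46),
                       "total": (-400.02, 19.02)},
    ("CCD4b", "LUT"): {"elect": (-119.87, 23.65), "vdw": (-331.35, 17.78),
                       "total": (-451.22, 24.61)},
    ("CCD4b", "RRX"): {"elect": (-76.22, 12.89), "vdw": (-350.70, 15.71),
                       "total": (-426.93, 20.45)},
    ("CCD4b", "ZEX"): {"elect": (-121.58, 25.71), "vdw": (-348.27, 18.43),
                       "total": (-469.85, 26.72)},
    ("CCD4c", "3ON"): {"elect": (-137.52, 25.04), "vdw": (-257.66, 16.61),
                       "total": (-395.18, 24.23)},
    ("CCD4c", "ACR"): {"elect": (-29.88, 10.07), "vdw": (-355.33, 14.78),
                       "total": (-385.21, 17.95)},
    ("CCD4c", "BCR"): {"elect": (-32.91, 11.40), "vdw": (-346.46, 16.16),
                       "total": (-379.36, 21.21)},
    ("CCD4c", "LYC"): {"elect": (-36.42, 11.65), "vdw": (-363.98, 17.23),
                       "total": (-400.40, 19.95)},
    ("CCD4c", "LUT"): {"elect": (-137.28, 28.76), "vdw": (-318.32, 18.68),
                       "total": (-455.60, 26.78)},
    ("CCD4c", "RRX"): {"elect": (-83.85, 18.59), "vdw": (-329.94, 18.81),
                       "total": (-413.79, 23.63)},
    ("CCD4c", "ZEX"): {"elect": (-132.90, 23.44), "vdw": (-360.72, 18.69),
                       "total": (-493.62, 24.86)},
}

# (receptor, ligand) -> {"distances": {label: A}, "mmpbsa": (mean, sd)}
SITE_TABLE: Dict[Tuple[str, str], Dict] = {
    ("CCD4a", "ACR"): {"distances": {"C7": 9.3, "C8": 8.7, "C9": 8.4,
                                     "C10": 8.2, "C15": 10.6, "C15P": 11.9},
                       "mmpbsa": (-148.50, 14.88)},
    ("CCD4a", "BCR"): {"distances": {"C7": 8.2, "C8": 7.1, "C9": 6.3,
                                     "C10": 6.0, "C15": 8.0, "C15P": 9.2},
                       "mmpbsa": (-162.54, 17.60)},
    ("CCD4a", "LUT"): {"distances": {"C7": 9.5, "C8": 8.5, "C9": 8.6,
                                     "C10": 8.3, "C15": 11.2, "C15P": 11.9},
                       "mmpbsa": (-136.63, 17.78)},
    ("CCD4a", "RRX"): {"distances": {"C7": 7.4, "C8": 7.3, "C9": 7.3,
                                     "C10": 8.4, "C15": 10.9, "C15P": 11.2},
                       "mmpbsa": (-133.16, 18.15)},
    ("CCD4a", "ZEX"): {"distances": {"C7": 7.8, "C8": 7.04, "C9": 6.5,
                                     "C10": 7.4, "C15": 10.2, "C15P": 11.1},
                       "mmpbsa": (-124.20, 17.85)},
    ("CCD4b", "ACR"): {"distances": {"C7": 11.8, "C8": 12.3, "C9": 12.2,
                                     "C10": 11.4, "C15": 11.7, "C15P": 11.7},
                       "mmpbsa": (-123.18, 17.91)},
    ("CCD4b", "BCR"): {"distances": {"C7": 11.1, "C8": 11.2, "C9": 10.7,
                                     "C10": 9.5, "C15": 9.4, "C15P": 10.0},
                       "mmpbsa": (-142.60, 19.08)},
    ("CCD4b", "LUT"): {"distances": {"C7": 7.5, "C8": 7.1, "C9": 6.5,
                                     "C10": 7.3, "C15": 9.5, "C15P": 10.6},
                       "mmpbsa": (-119.18, 29.12)},
    ("CCD4b", "RRX"): {"distances": {"C7": 10.1, "C8": 9.9, "C9": 8.9,
                                     "C10": 7.8, "C15": 5.8, "C15P": 6.8},
                       "mmpbsa": (-150.19, 16.83)},
    ("CCD4b", "RRX*"): {"distances": {"C7": 8.9, "C8": 8.0, "C9": 6.8,
                                      "C10": 6.9, "C15": 7.9, "C15P": 8.6},
                        "mmpbsa": (-164.57, 15.74)},
    ("CCD4b", "ZEX"): {"distances": {"C7": 7.0, "C8": 6.7, "C9": 6.2,
                                     "C10": 7.1, "C15": 10.0, "C15P": 11.0},
                       "mmpbsa": (-88.43, 22.31)},
    ("CCD4c", "ACR"): {"distances": {"C7": 12.3, "C8": 12.0, "C9": 11.3,
                                     "C10": 10.0, "C15": 7.9, "C15P": 7.3},
                       "mmpbsa": (-106.32, 19.08)},
    ("CCD4c", "BCR"): {"distances": {"C7": 10.9, "C8": 9.9, "C9": 8.5,
                                     "C10": 8.2, "C15": 5.8, "C15P": 6.3},
                       "mmpbsa": (-92.58, 27.12)},
    ("CCD4c", "LUT"): {"distances": {"C7": 11.4, "C8": 12.2, "C9": 11.9,
                                     "C10": 11.6, "C15": 11.6, "C15P": 11.3},
                       "mmpbsa": (-105.77, 28.35)},
    ("CCD4c", "RRX"): {"distances": {"C7": 10.8, "C8": 11.2, "C9": 10.5,
                                     "C10": 9.8, "C15": 8.7, "C15P": 9.12},
                       "mmpbsa": (-128.21, 20.68)},
    ("CCD4c", "ZEX"): {"distances": {"C7": 12.2, "C8": 11.14, "C9": 9.93,
                                     "C10": 8.8, "C15": 6.4, "C15P": 6.8},
                       "mmpbsa": (-99.74, 19.03)},
}
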