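"""Physical constants, unit conventions and amino-acid reference data.

Unit conventions used throughout the package:

* lengths in nm (PDB I/O converts from/to Angstrom),
* diffusion coefficients in 1e-5 cm^2 s^-1 (= 1e-9 m^2 s^-1),
* viscosities in mPa s (= 1e-3 Pa s),
* temperatures in K, times in ps, masses in kg mol^-1.
"""

from __future__ import annotations

# CODATA Boltzmann constant, J K^-1
K_B = 1.380649e-23

# scale factors to SI for the package's working units
D_UNIT = 1.0e-9        # 1e-5 cm^2/s in m^2/s
ETA_UNIT = 1.0e-3      # mPa s in Pa s
NM = 1.0e-9            # nm in m

# unitless cubic-lattice self term of the periodic hydrodynamic correction.
# Recompute with ride.dynamics.compute_xi_ew; this literature value is the
# cached fallback.
XI_EW = 2.837298

# TIP3P water shear viscosity at 310.15 K used for the shipped
# hydrodiffusivity scales (mPa s).  This is an independently computed
# simulation value, not an interpolation of the temperature table.
ETA_TIP3P_310 = 0.275
T_PHYS = 310.15

# reference temperature of the Polson mass-relation baseline (K)
T_POLSON_REF = 293.15

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AAS = tuple(sorted(AA3_TO_1))

# residue names accepted as terminal capping groups (acetyl / N-methylamide)
CAP_RESIDUES = ("ACE", "NME", "NMA")

# average residue (amino-acid minus water) masses, g mol^-1
RESIDUE_MASS = {
    "GLY": 57.0519, "ALA": 71.0788, "SER": 87.0782, "PRO": 97.1167,
    "VAL": 99.1326, "THR": 101.1051, "CYS": 103.1388, "LEU": 113.1594,
    "ILE": 113.1594, "ASN": 114.1038, "ASP": 115.0886, "GLN": 128.1307,
    "LYS": 128.1741, "GLU": 129.1155, "MET": 131.1926, "HIS": 137.1411,
    "PHE": 147.1766, "ARG": 156.1875, "TYR": 163.1760, "TRP": 186.2132,
}
WATER_MASS = 18.0153
# acetyl CH3-C(=O)- and N-methylamide -NH-CH3 cap masses (heavy + H), g mol^-1
CAP_MASS = {"ACE": 43.0446, "NME": 30.0499, "NMA": 30.0499}


def stokes_einstein_radius_nm(d_1e5cm2s: float, temperature_k: float,
                              eta_mpas: float) -> float:
    """Hydrodynamic radius in nm from D (1e-5 cm^2/s), T (K), eta (mPa s)."""
    import math
    return (K_B * temperature_k
            / (6.0 * math.pi * eta_mpas * ETA_UNIT * d_1e5cm2s * D_UNIT)) / NM


def stokes_einstein_d(r_h_nm: float, temperature_k: float,
                      eta_mpas: float) -> float:
    """D in 1e-5 cm^2/s from R_H (nm), T (K), eta (mPa s)."""
    import math
    return (K_B * temperature_k
            / (6.0 * math.pi * eta_mpas * ETA_UNIT * r_h_nm * NM)) / D_UNIT
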