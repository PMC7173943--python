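"""Shared parameter tables: residue codes, radii, reference SASA, side-chain
centroid geometry, and Ramachandran basin priors."""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # O-sulfotyrosine: tyrosine with a sulfated phenol oxygen (formal charge -1)
    "TYS": "y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

STANDARD_RES_TYPES = frozenset(AA3_TO_1)

#: van der Waals radii by element (Å), used for SASA and the reduced energy model
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum accessible surface area per residue type (Å²),
#: Tien et al. 2013 values, used to normalize per-residue SASA to a fraction.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "TYS": 263.0,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

#: Reduced side-chain representation: Cβ plus a single centroid pseudo-atom.
#: Per residue type: (Cβ→centroid distance Å, centroid radius Å, formal charge).
#: Gly has no side chain; Ala's side chain is Cβ itself.
SIDECHAIN_CENTROID = {
    "ARG": (4.0, 2.0, +1.0), "LYS": (3.5, 1.9, +1.0), "HIS": (2.9, 2.0, 0.0),
    "ASP": (1.9, 1.8, -1.0), "GLU": (2.6, 1.9, -1.0),
    "SER": (1.3, 1.6, 0.0), "THR": (1.3, 1.8, 0.0),
    "ASN": (1.9, 1.8, 0.0), "GLN": (2.6, 1.9, 0.0), "CYS": (1.8, 1.8, 0.0),
    "VAL": (1.2, 1.9, 0.0), "ILE": (1.8, 2.0, 0.0), "LEU": (2.0, 2.0, 0.0),
    "MET": (2.4, 2.0, 0.0), "PHE": (2.9, 2.2, 0.0), "TYR": (3.2, 2.3, 0.0),
    "TRP": (3.2, 2.4, 0.0), "PRO": (1.2, 1.8, 0.0),
    "TYS": (3.2, 2.3, -1.0),
}

#: Ramachandran basin prior for biased backbone moves:
#: name -> (phi mean, psi mean, sigma) in degrees. Uniform basin selection.
RAMACHANDRAN_BASINS = {
    "beta": (-139.0, 135.0, 20.0),
    "alphaR": (-63.0, -42.0, 10.0),
    "alphaL": (57.0, 47.0, 12.0),
    "ppii": (-75.0, 150.0, 15.0),
}

# Ideal backbone geometry (Engh-Huber-like) for ab initio chain construction
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0
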