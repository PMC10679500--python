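"""Physical constants and lookup tables shared across the toolkit.

All masses are in daltons. Monoisotopic residue masses are derived from the
elemental composition of each amino-acid *residue* (the free amino acid minus
one water), using CODATA/IUPAC 2021 atomic masses:

    H = 1.0078250319, C = 12.0, N = 14.0030740052, O = 15.9949146221,
    S = 31.97207069

e.g. glycine residue C2H3NO = 57.021464 Da; a free peptide adds one water
(H2O = 18.010565 Da) to the sum of its residue masses.
"""

from __future__ import annotations

WATER_MONO = 18.0105646863
WATER_AVG = 18.01528
PROTON_MASS = 1.007276466

#: gas constant in kcal mol^-1 K^-1 (thermal-unfolding model)
R_KCAL = 1.987e-3

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: monoisotopic residue masses (residue = amino acid - H2O)
MONO_RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: average residue masses (IUPAC 2021 atomic weights)
AVG_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: monoisotopic monosaccharide residue masses (residue = sugar - H2O)
#: Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, NeuAc C11H17NO8, Pent C5H8O4
MONOSACCHARIDE_MASS = {
    "hexnac": 203.079373,
    "hex": 162.052824,
    "dhex": 146.057909,
    "neuac": 291.095417,
    "pent": 132.042259,
}

#: pKa tables for isoelectric-point calculation.  Keys: termini and ionizable
#: side chains.  "emboss" mirrors the EMBOSS iep defaults; "sillero" is the
#: classic Sillero & Ribeiro (1989) set.
PKA_SETS = {
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "sillero": {
        "n_term": 8.2, "c_term": 3.2,
        "C": 9.0, "D": 4.0, "E": 4.5, "H": 6.4,
        "K": 10.4, "R": 12.0, "Y": 10.0,
    },
}

#: residues carrying a positive / negative formal charge at physiological pH
POSITIVE_RESIDUES = ("ARG", "LYS")
NEGATIVE_RESIDUES = ("ASP", "GLU")

#: van der Waals radii (Bondi) for SASA sampling, by element
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "FE": 1.52, "CA": 1.97, "MG": 1.73, "CL": 1.75,
    "NA": 2.27, "K": 2.75, "ZN": 1.39, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

#: maximum accessible surface area per residue (Tien et al. 2013, theoretical),
#: used to turn absolute side-chain SASA into relative accessibility
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: general-position multiplicity of the space groups the toolkit encounters
SPACE_GROUP_MULTIPLICITY = {
    "P 1": 1, "P1": 1,
    "P 21": 2, "P21": 2,
    "C 2": 4, "C2": 4,
    "P 21 21 2": 4,
    "P 21 21 21": 4, "P212121": 4,
    "P 2 2 2": 4,
    "C 2 2 21": 8,
    "I 4": 8, "P 43 21 2": 8, "P 41 21 2": 8,
}
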