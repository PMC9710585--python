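"""Amino-acid reference tables.

Fixed constants used across the feature and geometry code: one/three letter
codes, the theoretical maximum solvent accessibility per residue type (for
converting ASA to relative ASA), the overlapping physico-chemical class
membership sets, and side-chain/terminal pKa values for isoelectric-point
calculation.
"""

from __future__ import annotations

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common nonstandard residues mapped to their standard parent; anything not
# listed here and not standard is dropped on read (with a warning).
NONSTANDARD_PARENT = {
    "MSE": "MET",
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

# Theoretical maximum ASA (A^2) per residue type (Gly-X-Gly context,
# Tien et al. 2013 "theoretical" column); used for RSA = ASA / max.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Overlapping physico-chemical classes (Taylor classification as used by the
# seqinr AAstat convention), restricted to the 20 standard amino acids.
PHYSCHEM_CLASSES = {
    "tiny": set("ACGST"),
    "small": set("ACDGNPSTV"),
    "aliphatic": set("ILV"),
    "aromatic": set("FHWY"),
    "nonpolar": set("ACFGILMPVWY"),
    "polar": set("DEHKNQRST"),
    "charged": set("DEHKR"),
    "basic": set("HKR"),
    "acidic": set("DE"),
}
PHYSCHEM_ORDER = [
    "tiny", "small", "aliphatic", "aromatic", "nonpolar",
    "polar", "charged", "basic", "acidic",
]

# EMBOSS pKa set for isoelectric-point bisection.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
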