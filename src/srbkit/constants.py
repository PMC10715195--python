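"""Shared amino-acid tables and radii.

Coordinates are 1-based inclusive everywhere in this package, matching the
text formats it consumes (domain-hit tables, TM tables, PDB residue numbers).
"""

# The 20 canonical residues, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Van der Waals radii (Å) used by the cavity detector; standard Bondi-style values.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
VDW_DEFAULT = 1.70
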