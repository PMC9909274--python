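"""Amino-acid alphabet and reference property scales.

The 20-letter alphabet ``ALPHABET`` fixes the row order of every
per-amino-acid matrix in this package.  The default physicochemical table
bundles five canonical literature scales (hydrophobicity, polarizability,
polarity, helix propensity as a secondary-structure scale, and codon
multiplicity); it is a convenience default only — every entry point that
consumes physicochemical values accepts a user table instead.
"""

from __future__ import annotations

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Kyte-Doolittle hydropathy.
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Charton side-chain polarizability.
POLARIZABILITY = {
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
}

# Grantham polarity.
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

# Chou-Fasman alpha-helix propensity (secondary-structure scale).
HELIX_PROPENSITY = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

# Number of codons encoding each amino acid (codon diversity).
CODON_COUNT = {
    "A": 4, "R": 6, "N": 2, "D": 2, "C": 2,
    "Q": 2, "E": 2, "G": 4, "H": 2, "I": 3,
    "L": 6, "K": 2, "M": 1, "F": 2, "P": 4,
    "S": 6, "T": 4, "W": 1, "Y": 2, "V": 4,
}

# Theoretical maximum accessible surface area per residue type (Å²),
# used by the generator to turn an ASA-like value into a relative one.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

PHYSCHEM_PROPERTIES = (
    "hydrophobicity",
    "polarizability",
    "polarity",
    "secondary_structure",
    "codon_diversity",
)

GEOMETRIC_PROPERTIES = ("ASA", "RASA", "ECA", "ICA", "EVA")


def default_physchem_rows() -> dict[str, list[float]]:
    """The default 20 x 5 physicochemical table as {letter: 5 values}."""
    return {
        aa: [
            HYDROPHOBICITY[aa],
            POLARIZABILITY[aa],
            POLARITY[aa],
            HELIX_PROPENSITY[aa],
            float(CODON_COUNT[aa]),
        ]
        for aa in ALPHABET
    }
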