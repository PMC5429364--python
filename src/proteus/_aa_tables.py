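"""Amino-acid constant tables.

All feature code uses a single fixed amino-acid order: alphabetical by
one-letter code. Parsers permute whatever column order a file uses into
this order, so downstream code never sees a file dialect.
"""

from __future__ import annotations

import numpy as np

#: Canonical internal order (alphabetical one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Ambiguity / non-standard codes tolerated in sequences. They contribute
#: zero to composition and property counts.
AMBIGUOUS = set("XBZUJO*")

#: Column order of PSI-BLAST ASCII PSSM files (the -Q dialect).
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Polarity classes: non-polar / polar / acidic-polar / basic-polar.
POLARITY_NONPOLAR = set("AVLIMFWPG")
POLARITY_POLAR = set("STCYNQ")
POLARITY_ACIDIC = set("DE")
POLARITY_BASIC = set("KRH")

# Charge classes: positive / negative / neutral.
CHARGE_POSITIVE = set("KRH")
CHARGE_NEGATIVE = set("DE")
CHARGE_NEUTRAL = set(AA_ORDER) - CHARGE_POSITIVE - CHARGE_NEGATIVE

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Average residue mass in Da (monoisotopic-free, water subtracted).
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes in AA_ORDER; ambiguity codes -> -1."""
    return np.array([AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)


def _vector(table: dict[str, float]) -> np.ndarray:
    return np.array([table[aa] for aa in AA_ORDER])


KD_VECTOR = _vector(KYTE_DOOLITTLE)
MASS_VECTOR = _vector(RESIDUE_MASS)

# Class membership indicator matrices over AA_ORDER, used by the vectorised
# property features: rows = classes, columns = amino acids.
POLARITY_CLASSES = ("nonpolar", "polar", "acidic", "basic")
POLARITY_MATRIX = np.array(
    [[aa in cls for aa in AA_ORDER]
     for cls in (POLARITY_NONPOLAR, POLARITY_POLAR, POLARITY_ACIDIC, POLARITY_BASIC)],
    dtype=float,
)
CHARGE_CLASSES = ("positive", "negative", "neutral")
CHARGE_MATRIX = np.array(
    [[aa in cls for aa in AA_ORDER]
     for cls in (CHARGE_POSITIVE, CHARGE_NEGATIVE, CHARGE_NEUTRAL)],
    dtype=float,
)
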