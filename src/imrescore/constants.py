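"""Physical constants, residue compositions and physicochemical scales.

Monoisotopic element masses follow the NIST/CODATA values commonly used in
proteomics software. Residue monoisotopic masses are derived from the
elemental formulas so that residue, peptide and fragment masses are always
internally consistent.
"""

from __future__ import annotations

# Monoisotopic element masses (Da)
ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

PROTON_MASS = 1.00727646677
WATER_MASS = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]

# Residue (amino-acid minus water) elemental compositions
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


def formula_mass(formula: dict[str, float]) -> float:
    """Monoisotopic mass of an elemental composition (fractional counts allowed)."""
    return sum(ELEMENT_MASS[el] * n for el, n in formula.items())


RESIDUE_MASS: dict[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULA.items()
}

# Common modifications: name -> (monoisotopic mass delta, composition delta).
# Names are matched case-insensitively when parsing peptidoform strings.
MODIFICATIONS: dict[str, tuple[float, dict[str, int]]] = {
    "carbamidomethyl": (57.02146, {"C": 2, "H": 3, "N": 1, "O": 1}),
    "oxidation": (15.99491, {"O": 1}),
    "acetyl": (42.01057, {"C": 2, "H": 2, "O": 1}),
    "phospho": (79.96633, {"H": 1, "O": 3, "P": 1}),
    "methyl": (14.01565, {"C": 1, "H": 2}),
    "dimethyl": (28.03130, {"C": 2, "H": 4}),
    "deamidation": (0.98402, {"H": -1, "N": -1, "O": 1}),
}

# Physicochemical scales used by the cleavage-site encoder.
# Hydrophobicity: Kyte-Doolittle.
HYDROPHOBICITY: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

# Gas-phase basicity-like scale (relative, arbitrary units centred on 0).
BASICITY: dict[str, float] = {
    "A": 0.0, "C": 0.1, "D": -0.6, "E": -0.5, "F": 0.3, "G": -0.2,
    "H": 1.6, "I": 0.2, "K": 2.0, "L": 0.2, "M": 0.3, "N": 0.4,
    "P": 0.6, "Q": 0.5, "R": 2.5, "S": 0.0, "T": 0.1, "V": 0.1,
    "W": 0.6, "Y": 0.3,
}

# Chou-Fasman alpha-helix propensity.
HELICITY: dict[str, float] = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69,
}

# Isoelectric point of the free amino acid.
PI: dict[str, float] = {
    "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
    "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
    "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
    "W": 5.89, "Y": 5.66,
}
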