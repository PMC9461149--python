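"""Per-amino-acid reference tables.

MAX_ACCESSIBILITY holds the maximum solvent-accessible surface area (A^2) of
residue X in a Gly-X-Gly tripeptide, from Miller, Janin, Lesk & Chothia,
J. Mol. Biol. 196 (1987) 641-656 (Table 2). Relative accessibility is the
DSSP accessibility divided by this value.

KYTE_DOOLITTLE is the hydropathy index of Kyte & Doolittle, J. Mol. Biol.
157 (1982) 105-132. Residues with an index strictly greater than 2 are
treated as hydrophobic by the silhouette model-selection step.
"""

from __future__ import annotations

MAX_ACCESSIBILITY: dict[str, float] = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

KYTE_DOOLITTLE: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

#: Common non-standard residues mapped to their closest standard parent.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",  # hydroxyproline
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "MLY": "LYS",
    "CSO": "CYS",
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def standardize_resname(name: str) -> str | None:
    """Map a residue name to a standard 3-letter code, or None if unknown."""
    name = name.strip().upper()
    if name in MAX_ACCESSIBILITY:
        return name
    return NONSTANDARD_PARENT.get(name)
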