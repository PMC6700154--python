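"""Amino-acid alphabet, group definitions and default side-chain radii.

Everything in the package indexes amino acids by their position in
:data:`AA_ORDER` (alphabetical one-letter codes).
"""

from __future__ import annotations

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_AA = len(AA_ORDER)

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common modified residues mapped onto their parent standard type.
NONSTANDARD_MAP = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Physicochemical groups used for pooled (group) potentials.
GROUP_MEMBERS = {
    "positive": ("K", "R"),
    "negative": ("E", "D"),
    "aromatic": ("F", "Y", "W"),
    "aliphatic": ("I", "V", "L"),
    "polar": ("Q", "N", "S", "T"),
    "small": ("G", "A"),
    "sulfur": ("C", "M"),
}

# Default side-chain radii (Å): mean distance of side-chain heavy atoms to
# their geometric center, from idealized side-chain geometry. Single-atom side
# chains (Ala) and Gly (no side chain, center taken at CA) have radius 0 by
# the definition itself. Used only for amino-acid types absent from the
# structures handed to estimate_residue_radii.
DEFAULT_RADII = {
    "A": 0.0, "C": 0.87, "D": 1.12, "E": 1.43, "F": 1.70,
    "G": 0.0, "H": 1.52, "I": 1.10, "K": 1.72, "L": 1.15,
    "M": 1.45, "N": 1.14, "P": 0.93, "Q": 1.44, "R": 2.05,
    "S": 0.74, "T": 0.87, "V": 0.92, "W": 2.01, "Y": 1.98,
}


def one_letter(res_name: str) -> str | None:
    """Map a PDB residue name to a canonical one-letter code, or None."""
    name = res_name.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    return NONSTANDARD_MAP.get(name)
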