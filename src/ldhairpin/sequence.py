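"""Residue bookkeeping for the UBXD8 membrane-proximal region.

Numbering is full-length human UBXD8 (FAF2), 1-based; intervals are
inclusive. Only the wild-type identities that matter for the assays are
recorded here; positions without a recorded identity map to ``X``.
"""

from __future__ import annotations

# Residue range probed by the single-cysteine accessibility scan.
SCAN_START = 80
SCAN_END = 128

# Wild-type identities of positions referenced by the assays (one-letter).
KNOWN_WT: dict[int, str] = {
    80: "S", 81: "Y", 85: "R", 88: "P", 89: "R",
    90: "G", 91: "L", 92: "L", 93: "G", 94: "W",
    96: "Y", 101: "L", 102: "P", 104: "R", 107: "Y",
    108: "Y", 109: "T", 111: "L", 113: "I", 114: "F",
    115: "R", 116: "F", 118: "L", 119: "R", 122: "R",
    123: "P", 124: "D", 127: "S", 128: "R", 130: "T",
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def wt_aa(residue_index: int) -> str:
    """One-letter wild-type code at ``residue_index`` (``X`` if unknown)."""
    return KNOWN_WT.get(int(residue_index), "X")


def wt_aa3(residue_index: int) -> str:
    """Three-letter wild-type code at ``residue_index`` (``UNK`` if unknown)."""
    return _ONE_TO_THREE[wt_aa(residue_index)]
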