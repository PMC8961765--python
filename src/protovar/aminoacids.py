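"""Residue-level constant tables used by the feature calculators.

All tables are keyed by one-letter amino-acid codes and cover exactly the
20 canonical residues.  They are deliberately plain dicts so that a user
can override any of them (e.g. from a YAML config) without touching code.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Residue volumes in cubic angstroms (Richards 1974 partial-volume scale).
RICHARDS_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# The seven strongly hydrophobic residues. The hydrophobicity scale we
# follow groups the aliphatic and large aromatic/sulfur side chains as
# "strong"; every other residue counts as polar for transition purposes.
STRONG_HYDROPHOBIC = frozenset("VILFMWC")

# Side-chain formal charge at physiological pH.
CHARGE = {aa: "neutral" for aa in CANONICAL_AA}
CHARGE.update({"K": "positive", "R": "positive", "H": "positive",
               "D": "negative", "E": "negative"})

# Total accessible surface areas (A^2) of residue X in an extended
# Ala-X-Ala tripeptide (Naccess-style reference state, probe 1.4 A).
_TRIPEPTIDE_TOTAL_ASA = {
    "A": 107.95, "R": 238.76, "N": 143.94, "D": 140.39, "C": 134.28,
    "Q": 178.50, "E": 172.25, "G": 80.10, "H": 182.88, "I": 175.12,
    "L": 178.63, "K": 200.81, "M": 194.15, "F": 199.48, "P": 136.13,
    "S": 116.50, "T": 139.27, "W": 249.36, "Y": 212.76, "V": 151.44,
}

# Side-chain reference areas: total minus the ~38.54 A^2 main-chain
# contribution of the central residue in the extended reference state.
# Glycine has no side chain; its C-alpha serves as a pseudo side chain.
_MAINCHAIN_ASA = 38.54
SIDECHAIN_REF_ASA = {
    aa: round(total - _MAINCHAIN_ASA, 2)
    for aa, total in _TRIPEPTIDE_TOTAL_ASA.items()
}
SIDECHAIN_REF_ASA["G"] = 32.33  # C-alpha convention

# Atom names considered part of the backbone when splitting SASA.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


def validate_aa(aa: str) -> str:
    """Return ``aa`` upper-cased, or raise ``ValueError`` if non-canonical."""
    aa = aa.strip().upper()
    if len(aa) == 3:
        aa = AA3_TO_1.get(aa, aa)
    if aa not in CANONICAL_AA or len(aa) != 1:
        raise ValueError(f"non-canonical amino acid: {aa!r}")
    return aa
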