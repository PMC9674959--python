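"""Amino-acid property tables used for sequence-based featurization.

The tables are plain dictionaries so an alternate scale can be swapped in by
passing a different mapping to the feature extractors.
"""

from __future__ import annotations

from functools import lru_cache

#: The 20 canonical amino acids, one-letter codes, alphabetical.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Net side-chain charge at pH 7 (His treated as neutral).
SIDE_CHAIN_CHARGE: dict[str, int] = {
    **{aa: 0 for aa in CANONICAL_AA},
    "D": -1, "E": -1, "K": 1, "R": 1,
}

#: Residue volumes in cubic Angstroms (Zamyatnin).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def blosum62_score(ref: str, alt: str) -> float:
    """BLOSUM62 substitution score for a ref->alt amino-acid change."""
    return float(_blosum62()[ref, alt])
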