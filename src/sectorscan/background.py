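"""Shared constants: amino-acid alphabet, background frequencies, sector palette.

The background distribution is the standard database composition used by
covariation analyses of protein alignments (Robinson-style frequencies over
the 20 canonical amino acids). It can be overridden anywhere a ``q`` argument
is accepted.
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter alphabet, alphabetical order. Index into all
#: frequency arrays follows this ordering.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

N_AA: int = len(AA_ALPHABET)

# Background amino-acid frequencies (order follows AA_ALPHABET). Values sum
# to 1 after the explicit normalization below.
_RAW_BACKGROUND = np.array(
    [
        0.073,  # A
        0.025,  # C
        0.050,  # D
        0.061,  # E
        0.042,  # F
        0.072,  # G
        0.023,  # H
        0.053,  # I
        0.064,  # K
        0.089,  # L
        0.023,  # M
        0.043,  # N
        0.052,  # P
        0.040,  # Q
        0.052,  # R
        0.073,  # S
        0.056,  # T
        0.063,  # V
        0.013,  # W
        0.033,  # Y
    ]
)

BACKGROUND_FREQS: np.ndarray = _RAW_BACKGROUND / _RAW_BACKGROUND.sum()
BACKGROUND_FREQS.setflags(write=False)

#: Sector color palette; labels are assigned to sectors in this fixed order
#: (sector rank is positional, by associated eigenvalue — color carries no
#: semantic meaning).
SECTOR_PALETTE: tuple[str, ...] = (
    "red",
    "blue",
    "green",
    "yellow",
    "purple",
    "orange",
    "cyan",
    "magenta",
    "salmon",
    "gray",
)

#: Three-letter to one-letter residue code translation (unknowns map to 'X').
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # common modified residues seen in coordinate files
    "MSE": "M", "SEC": "C", "PYL": "K",
}

ONE_TO_THREE: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


def validate_background(q: np.ndarray) -> np.ndarray:
    """Validate and return a background frequency vector.

    Raises ``ValueError`` unless ``q`` has 20 strictly positive entries
    summing to 1 within 1e-9.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (N_AA,):
        raise ValueError(f"background frequencies must have shape ({N_AA},), got {q.shape}")
    if not np.all(q > 0):
        raise ValueError("background frequencies must be strictly positive")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError(f"background frequencies must sum to 1 (got {q.sum():.12f})")
    return q
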