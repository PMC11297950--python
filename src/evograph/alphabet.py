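"""Amino-acid alphabet shared across the package.

The working alphabet has q = 21 states: the 20 standard amino acids in a
fixed order followed by the gap character.  The unknown residue ``X`` is not
a state of its own in frequency counts; it contributes a fractional count of
1/20 to each amino-acid state so that unknowns never create spurious
couplings.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP  # the q states used in statistics
Q = len(ALPHABET)  # 21

GAP_STATE = Q - 1

# integer codes: 0..19 amino acids, 20 gap, 21 unknown
_CODES = {c: i for i, c in enumerate(ALPHABET)}
UNKNOWN_CODE = Q
_CODES[UNKNOWN] = UNKNOWN_CODE

SEQUENCE_ALPHABET = set(AMINO_ACIDS) | {UNKNOWN}
MSA_ALPHABET = SEQUENCE_ALPHABET | {GAP}


def normalize_char(c: str) -> str:
    """Map an arbitrary residue character to the working alphabet."""
    c = c.upper()
    if c in MSA_ALPHABET:
        return c
    if c in ".~":
        return GAP
    return UNKNOWN


def encode(row: str) -> np.ndarray:
    """Encode an aligned row as integer codes (0..19 aa, 20 gap, 21 unknown)."""
    return np.fromiter((_CODES[c] for c in row), dtype=np.int8, count=len(row))


def one_hot(codes: np.ndarray) -> np.ndarray:
    """One-hot encoding over the q = 21 states; unknowns spread 1/20 over amino acids.

    Rows always sum to one, which keeps single-site and pair frequency
    marginals exactly consistent.
    """
    codes = np.asarray(codes)
    out = np.zeros(codes.shape + (Q,), dtype=float)
    known = codes < Q
    out[known, codes[known].astype(int)] = 1.0
    out[~known, :GAP_STATE] = 1.0 / (Q - 1)
    return out
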