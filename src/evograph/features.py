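"""Per-residue node features.

The network consumes an L×D feature matrix per protein.  In production this
is a language-model embedding supplied as an external numeric text file
(one residue per row); for self-contained experiments two deterministic
featurizers are provided: one-hot encoding and a seeded per-letter random
projection that mimics the width of a transformer embedding at any D.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, SEQUENCE_ALPHABET, UNKNOWN

_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray  # (L, D)
    featurizer_tag: str  # onehot | randproj | external

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("node features must be an L×D matrix")
        if not np.isfinite(v).all():
            raise ValueError("node features must be finite")
        self.values = v

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"illegal residue characters in sequence: {sorted(bad)}")


def onehot_features(sequence: str) -> NodeFeatureMatrix:
    """One-hot features, D = 21; 'X' spreads 1/20 over the amino-acid slots."""
    _check_sequence(sequence)
    L = len(sequence)
    values = np.zeros((L, 21))
    for i, c in enumerate(sequence):
        if c == UNKNOWN:
            values[i, :20] = 1.0 / 20.0
        else:
            values[i, _AA_INDEX[c]] = 1.0
    return NodeFeatureMatrix(values=values, featurizer_tag="onehot")


def randproj_features(sequence: str, D: int = 1280, seed: int = 0) -> NodeFeatureMatrix:
    """Seeded per-letter random projection features.

    Every letter (20 amino acids plus 'X') owns a fixed D-vector drawn from a
    standard normal; row i is the vector of residue i's letter.  Purely a
    function of (letter, seed) — position plays no role.
    """
    if D < 1:
        raise ValueError("feature dimension D must be >= 1")
    _check_sequence(sequence)
    rng = np.random.default_rng(seed)
    table = rng.standard_normal((21, D))
    index = {**_AA_INDEX, UNKNOWN: 20}
    values = table[[index[c] for c in sequence]]
    return NodeFeatureMatrix(values=values, featurizer_tag="randproj")


def sinusoidal_positions(L: int, D: int = 8, base: float = 100.0) -> np.ndarray:
    """Sinusoidal positional encoding, shape (L, D).

    Interleaved sin/cos at geometrically spaced frequencies, the standard
    transformer construction.  Used to emulate the position-awareness of
    learned sequence embeddings in synthetic feature matrices.
    """
    if D < 2 or D % 2:
        raise ValueError("positional dimension D must be even and >= 2")
    pe = np.zeros((L, D))
    pos = np.arange(L)[:, None]
    div = base ** (np.arange(0, D, 2) / D)
    pe[:, 0::2] = np.sin(pos / div)
    pe[:, 1::2] = np.cos(pos / div)
    return pe


def load_external_features(path: str | Path, expected_L: int) -> NodeFeatureMatrix:
    """Load an externally computed embedding (whitespace/tab-delimited text).

    The row count must equal the protein length; any non-numeric cell is a
    parse error.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as err:
        raise ValueError(f"non-numeric value in feature file {path}: {err}") from err
    if values.shape[0] != expected_L:
        raise ValueError(
            f"feature file {path} has {values.shape[0]} rows, "
            f"expected {expected_L} (protein length)"
        )
    return NodeFeatureMatrix(values=values, featurizer_tag="external")
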