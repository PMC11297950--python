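"""Evolutionary coupling inference by mean-field direct coupling analysis.

The coupling strength between two alignment columns is the Frobenius norm,
in zero-sum gauge, of the corresponding block of the negative inverse of the
regularized connected-correlation matrix, followed by the average product
correction (APC) that removes phylogenetic/entropic background.  Scores are
normalized to [0, 1] per protein and binarized at a quality threshold to
form the EVC-channel graph adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import Q
from .msa import WeightedFrequencies


class CouplingError(RuntimeError):
    """Numerical failure during coupling inference."""


@dataclass
class CouplingMatrix:
    """Symmetric L×L residue–residue coupling strengths, zero diagonal."""

    scores: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("coupling scores must be a square matrix")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.abs(np.diag(s)) > 1e-12):
            raise ValueError("coupling matrix must have zero diagonal")
        self.scores = s

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class BinaryAdjacency:
    """Symmetric binary graph adjacency with zero diagonal."""

    entries: np.ndarray
    source: str = "EVC"
    threshold: float = 0.2

    def __post_init__(self) -> None:
        a = np.asarray(self.entries)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        self.entries = a.astype(float)

    @property
    def length(self) -> int:
        return self.entries.shape[0]


def apc_correction(scores: np.ndarray) -> np.ndarray:
    """Average product correction: S_ij − S_i·S_j/S̄, negatives clipped to 0."""
    L = scores.shape[0]
    off = scores.copy()
    np.fill_diagonal(off, 0.0)
    row_mean = off.sum(axis=1) / (L - 1)
    total_mean = off.sum() / (L * (L - 1))
    if total_mean <= 0:
        corrected = off
    else:
        corrected = off - np.outer(row_mean, row_mean) / total_mean
    corrected = np.clip(corrected, 0.0, None)
    np.fill_diagonal(corrected, 0.0)
    return corrected


def infer_couplings(freqs: WeightedFrequencies, apc: bool = True) -> CouplingMatrix:
    """Infer the L×L evolutionary coupling matrix from alignment statistics.

    Mean-field inverse-covariance estimate over the first q−1 states (the
    gap state is excluded from the coupling norm to avoid gap-driven edges):
    couplings e = −C⁻¹ with C the connected correlation f_ij − f_i f_j;
    per-pair score = Frobenius norm of the zero-sum-gauge (i,j) block;
    APC applied unless disabled.
    """
    L = freqs.length
    if L < 2:
        raise ValueError("coupling inference needs L >= 2 columns")
    k = Q - 1  # amino-acid states only
    f_i = freqs.f_i[:, :k]
    f_ij = freqs.f_ij[:, :, :k, :k]
    C = f_ij - f_i[:, None, :, None] * f_i[None, :, None, :]
    C = C.transpose(0, 2, 1, 3).reshape(L * k, L * k)
    try:
        e = -np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise CouplingError(
            "covariance matrix is singular; use a larger pseudocount "
            "(lambda > 0) or a deeper alignment"
        ) from err
    e = 0.5 * (e + e.T)
    blocks = e.reshape(L, k, L, k).transpose(0, 2, 1, 3)
    gauged = (
        blocks
        - blocks.mean(axis=2, keepdims=True)
        - blocks.mean(axis=3, keepdims=True)
        + blocks.mean(axis=(2, 3), keepdims=True)
    )
    scores = np.sqrt((gauged**2).sum(axis=(2, 3)))
    scores = 0.5 * (scores + scores.T)
    np.fill_diagonal(scores, 0.0)
    if apc:
        scores = apc_correction(scores)
    return CouplingMatrix(scores=scores, normalized=False)


def normalize_couplings(c: CouplingMatrix) -> CouplingMatrix:
    """Scale couplings so the maximum off-diagonal entry is 1 (per protein).

    An all-zero matrix is returned unchanged, flagged normalized.
    """
    peak = c.scores.max()
    if peak <= 0:
        return CouplingMatrix(scores=c.scores.copy(), normalized=True)
    return CouplingMatrix(scores=c.scores / peak, normalized=True)


def threshold_adjacency(c: CouplingMatrix, threshold: float = 0.2) -> BinaryAdjacency:
    """Binarize a normalized coupling matrix: entries >= threshold become edges."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not c.normalized:
        raise ValueError("adjacency thresholding expects a normalized coupling matrix")
    entries = (c.scores >= threshold).astype(float)
    np.fill_diagonal(entries, 0)
    return BinaryAdjacency(entries=entries, source="EVC", threshold=threshold)


def write_couplings_tsv(c: CouplingMatrix, path: str | Path) -> None:
    """Write couplings as TSV (i, j, score), 1-based, i < j."""
    L = c.length
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1}\t{j + 1}\t{c.scores[i, j]:.6f}\n")


def write_adjacency_tsv(adj: BinaryAdjacency, path: str | Path) -> None:
    """Write adjacency as edge-list TSV (i, j), 1-based, i < j."""
    L = adj.length
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i in range(L):
            for j in range(i + 1, L):
                if adj.entries[i, j]:
                    fh.write(f"{i + 1}\t{j + 1}\n")


def read_couplings_tsv(path: str | Path, length: int) -> CouplingMatrix:
    scores = np.zeros((length, length))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("i\t"):
            raise ValueError("coupling TSV must start with an 'i\\tj\\tscore' header")
        for line in fh:
            i_s, j_s, v_s = line.split("\t")
            i, j, v = int(i_s) - 1, int(j_s) - 1, float(v_s)
            scores[i, j] = scores[j, i] = v
    peak = scores.max()
    return CouplingMatrix(scores=scores, normalized=bool(peak <= 1.0 + 1e-12))
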