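"""Multiple sequence alignment I/O, trimming, reweighting and statistics.

Alignments arrive either as plain aligned FASTA or as A3M (the dialect in
which lowercase letters and ``.`` mark insertions relative to the query's
match columns; removing them restores a rectangular alignment).  Downstream
coupling inference consumes weighted single-site and pair frequencies with a
uniform pseudocount, the standard substrate for mean-field direct coupling
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, GAP_STATE, Q, encode, normalize_char, one_hot


class MsaError(ValueError):
    """Malformed or empty alignment input."""


@dataclass
class MultipleSequenceAlignment:
    """A rectangular alignment over {20 amino acids, '-', 'X'}.

    ``query_index`` names the target protein whose residues index every
    downstream matrix; it defaults to the first record, matching the
    convention of homology-search outputs.
    """

    identifiers: list[str]
    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise MsaError("alignment must contain at least one sequence")
        if len(self.identifiers) != len(self.rows):
            raise MsaError("identifiers and rows differ in number")
        length = len(self.rows[0])
        if length < 1:
            raise MsaError("alignment columns L must be >= 1")
        for ident, row in zip(self.identifiers, self.rows):
            if len(row) != length:
                raise MsaError(
                    f"record '{ident}' has length {len(row)}, expected {length}"
                )
        if not 0 <= self.query_index < len(self.rows):
            raise MsaError(f"query_index {self.query_index} out of range")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_sequence(self) -> str:
        """Query row with gap columns removed (the target protein sequence)."""
        return self.query.replace(GAP, "")

    def codes(self) -> np.ndarray:
        """Integer-coded alignment, shape (M, L)."""
        return np.stack([encode(r) for r in self.rows])


@dataclass
class WeightedFrequencies:
    """Reweighted, pseudocounted column statistics of an alignment.

    ``f_i`` is (L, q); ``f_ij`` is (L, L, q, q) with the diagonal blocks
    pinned to diag(f_i) so that single- and pair-marginals agree exactly.
    """

    weights: np.ndarray
    f_i: np.ndarray
    f_ij: np.ndarray
    effective_depth: float
    pseudocount: float

    @property
    def length(self) -> int:
        return self.f_i.shape[0]


def _clean_row(raw: str, fmt: str) -> str:
    if fmt == "a3m":
        # lowercase letters and '.' are insertions relative to the query's
        # match columns; dropping them restores the rectangular alignment
        raw = "".join(c for c in raw if not (c.islower() or c == "."))
    return "".join(normalize_char(c) for c in raw)


def read_msa(path: str | Path, format: str | None = None) -> MultipleSequenceAlignment:
    """Read an aligned FASTA or A3M file.

    Parameters
    ----------
    path
        Alignment file.
    format
        ``"fasta"`` or ``"a3m"``; inferred from the file suffix when omitted
        (``.a3m`` -> a3m, anything else -> fasta).
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format '{format}'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MsaError(f"no sequences found in {path}")
    identifiers = [r.id for r in records]
    rows = [_clean_row(str(r.seq), format) for r in records]
    length = len(rows[0])
    for ident, row in zip(identifiers, rows):
        if len(row) != length:
            raise MsaError(
                f"record '{ident}' has length {len(row)} after normalization, "
                f"expected {length} (ragged alignment)"
            )
    return MultipleSequenceAlignment(identifiers=identifiers, rows=rows)


def write_msa(msa: MultipleSequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ident, row in zip(msa.identifiers, msa.rows):
            fh.write(f">{ident}\n{row}\n")


def trim_msa(
    msa: MultipleSequenceAlignment, max_gap_fraction: float = 0.8
) -> MultipleSequenceAlignment:
    """Drop low-quality rows whose gap fraction exceeds ``max_gap_fraction``.

    The inequality is strict — a row at exactly the threshold is retained —
    and the query row is never removed, so residue indices always cover the
    full target sequence.  Row order is preserved.
    """
    if not 0.0 < max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    keep: list[int] = []
    for s, row in enumerate(msa.rows):
        gap_fraction = row.count(GAP) / len(row)
        if s == msa.query_index or gap_fraction <= max_gap_fraction:
            keep.append(s)
    if len(keep) == 1 and msa.depth > 1:
        warnings.warn(
            "all non-query sequences were removed by gap trimming",
            stacklevel=2,
        )
    return MultipleSequenceAlignment(
        identifiers=[msa.identifiers[s] for s in keep],
        rows=[msa.rows[s] for s in keep],
        query_index=keep.index(msa.query_index),
    )


def compute_weights(
    msa: MultipleSequenceAlignment, identity_threshold: float = 0.8
) -> np.ndarray:
    """Redundancy weights: 1 / (number of rows at >= threshold identity, self included).

    Identity is the fraction of alignment columns with identical characters
    (gap matching gap counts).  This is the standard reweighting that defines
    the effective depth M_eff = sum of weights.
    """
    codes = msa.codes()
    M, L = codes.shape
    counts = np.zeros(M, dtype=float)
    chunk = max(1, int(2_000_000 // max(L, 1)))
    for start in range(0, M, chunk):
        block = codes[start : start + chunk]
        ident = (block[:, None, :] == codes[None, :, :]).mean(axis=2)
        counts[start : start + chunk] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def frequencies(
    msa: MultipleSequenceAlignment,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> WeightedFrequencies:
    """Weighted single-site and pair frequencies with uniform pseudocount λ.

    f_i(a)    = λ/q  + (1-λ) · weighted empirical frequency
    f_ij(a,b) = λ/q² + (1-λ) · weighted empirical pair frequency (i ≠ j)

    The gap is counted as the 21st state; unknown residues spread 1/20 over
    the amino-acid states.
    """
    if not 0.0 <= pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in [0, 1]")
    codes = msa.codes()
    M, L = codes.shape
    if weights is None:
        weights = np.ones(M, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (M,) or np.any(weights < 0):
        raise ValueError("weights must be M nonnegative reals")
    W = float(weights.sum())

    X = one_hot(codes).reshape(M, L * Q)
    f1 = (weights @ X).reshape(L, Q) / W
    pair = (weights[:, None] * X).T @ X / W  # (L*Q, L*Q)
    f2 = pair.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)

    lam = pseudocount
    f_i = lam / Q + (1.0 - lam) * f1
    f_ij = lam / (Q * Q) + (1.0 - lam) * f2
    # pin diagonal blocks: f_ii(a,b) = δ_ab f_i(a)
    idx = np.arange(L)
    states = np.arange(Q)
    f_ij[idx, idx] = 0.0
    f_ij[idx[:, None], idx[:, None], states[None, :], states[None, :]] = f_i
    return WeightedFrequencies(
        weights=weights, f_i=f_i, f_ij=f_ij, effective_depth=W, pseudocount=lam
    )


def conservation(freqs: WeightedFrequencies) -> np.ndarray:
    """Per-column conservation: 1 − H(f_i)/log q ∈ [0, 1].

    A fully conserved column scores 1, a uniform column 0.
    """
    f = np.clip(freqs.f_i, 1e-300, None)
    H = -(freqs.f_i * np.log(f)).sum(axis=1)
    return 1.0 - H / np.log(Q)


def write_conservation(scores: np.ndarray, path: str | Path) -> None:
    """Write conservation as TSV (position [1-based], score)."""
    with open(path, "w") as fh:
        fh.write("position\tconservation\n")
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.6f}\n")
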