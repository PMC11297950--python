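"""Residue communities from spectral analysis of the coupling matrix.

A community is a group of residues whose mutual couplings are stronger than
a structureless null expects — the coevolving "sectors" of the protein.
Significant eigenmodes of the normalized coupling matrix are selected
against a permutation null; each residue is hard-assigned to the mode on
which it loads most, provided the loading clears a flatness cutoff, and its
membership strength is the loading relative to the mode's peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .couplings import BinaryAdjacency, CouplingMatrix


@dataclass
class ResidueCommunity:
    members: list[int]  # 0-based residue indices
    strengths: dict[int, float]  # residue -> strength in (0, 1]
    eigenvalue: float


@dataclass
class ResidueCommunitySet:
    """Hard partition of (a subset of) residues into coupling communities."""

    communities: list[ResidueCommunity]
    length: int

    def membership(self) -> np.ndarray:
        """Community id per residue (-1 for unassigned), shape (L,)."""
        labels = np.full(self.length, -1, dtype=int)
        for k, comm in enumerate(self.communities):
            for i in comm.members:
                labels[i] = k
        return labels

    def strength_vector(self) -> np.ndarray:
        s = np.zeros(self.length)
        for comm in self.communities:
            for i, v in comm.strengths.items():
                s[i] = v
        return s


def _null_max_eigenvalue(
    scores: np.ndarray, n_null: int, rng: np.random.Generator
) -> float:
    """Largest eigenvalue over symmetric shuffles of the off-diagonal entries.

    Shuffling preserves the entry distribution exactly while destroying any
    block structure, giving a structureless reference spectrum.
    """
    L = scores.shape[0]
    iu = np.triu_indices(L, k=1)
    vals = scores[iu].copy()
    peak = -np.inf
    for _ in range(n_null):
        rng.shuffle(vals)
        null = np.zeros_like(scores)
        null[iu] = vals
        null += null.T
        peak = max(peak, float(np.linalg.eigvalsh(null)[-1]))
    return peak


def detect_communities(
    c: CouplingMatrix,
    max_k: int = 10,
    eig_threshold: float | str = "auto",
    loading_cutoff: float | None = None,
    n_null: int = 20,
    seed: int = 0,
) -> ResidueCommunitySet:
    """Detect residue communities in a normalized coupling matrix.

    Parameters
    ----------
    c
        Normalized, symmetric coupling matrix.
    max_k
        Maximum number of communities retained (strongest eigenvalues first).
    eig_threshold
        ``"auto"`` selects eigenmodes whose eigenvalue exceeds the maximum
        eigenvalue over ``n_null`` shuffled null matrices; a float fixes the
        cutoff directly.
    loading_cutoff
        Minimum |loading| for membership; defaults to 2/√L, twice the RMS
        loading of a flat eigenvector.
    """
    L = c.length
    if L < 3:
        warnings.warn("alignment too short for community detection (L < 3)", stacklevel=2)
        return ResidueCommunitySet(communities=[], length=L)
    if loading_cutoff is None:
        loading_cutoff = 2.0 / np.sqrt(L)
    scores = c.scores
    eigvals, eigvecs = np.linalg.eigh(scores)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if eig_threshold == "auto":
        rng = np.random.default_rng(seed)
        cutoff = _null_max_eigenvalue(scores, n_null, rng)
    else:
        cutoff = float(eig_threshold)
    retained = [k for k in range(L) if eigvals[k] > cutoff][:max_k]
    if not retained:
        return ResidueCommunitySet(communities=[], length=L)

    V = np.abs(eigvecs[:, retained])  # (L, n_retained)
    best = V.argmax(axis=1)
    best_loading = V[np.arange(L), best]
    communities: list[ResidueCommunity] = []
    for slot, k in enumerate(retained):
        members = [
            int(i)
            for i in range(L)
            if best[i] == slot and best_loading[i] >= loading_cutoff
        ]
        if len(members) < 2:
            continue
        peak = np.abs(eigvecs[:, k]).max()
        strengths = {i: float(np.abs(eigvecs[i, k]) / peak) for i in members}
        communities.append(
            ResidueCommunity(
                members=members, strengths=strengths, eigenvalue=float(eigvals[k])
            )
        )
    return ResidueCommunitySet(communities=communities, length=L)


def rc_adjacency(rcs: ResidueCommunitySet, threshold: float = 0.2) -> BinaryAdjacency:
    """RC-channel adjacency: i–j connected iff they share a community and
    min(strength_i, strength_j) >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    L = rcs.length
    entries = np.zeros((L, L))
    for comm in rcs.communities:
        kept = [i for i in comm.members if comm.strengths[i] >= threshold]
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                entries[kept[a], kept[b]] = entries[kept[b], kept[a]] = 1
    return BinaryAdjacency(entries=entries, source="RC", threshold=threshold)


def write_communities_tsv(rcs: ResidueCommunitySet, path: str | Path) -> None:
    """Write communities as TSV (community_id, residue [1-based], strength)."""
    with open(path, "w") as fh:
        fh.write("community\tresidue\tstrength\n")
        for k, comm in enumerate(rcs.communities, start=1):
            for i in sorted(comm.members):
                fh.write(f"{k}\t{i + 1}\t{comm.strengths[i]:.6f}\n")
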