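"""Seeded generators for every upstream input of the pipeline.

Three families of fixtures:

* alignments with planted covarying column pairs and a conservation
  profile — covariation is induced by copying a bijective image of one
  column's letter into its partner with probability ρ, which gives
  analytically controllable mutual information;
* labeled protein datasets in which each function label is caused by a
  residue-class pattern at designated functional sites, and those sites
  form planted blocks in the channel adjacencies (the known ground truth
  against which residue-level scoring is judged);
* prediction/truth fixtures of tunable quality for the evaluation metrics.

Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, GAP
from .features import randproj_features, sinusoidal_positions
from .graphnet import ProteinGraph
from .metrics import EvaluationSet
from .msa import MultipleSequenceAlignment
from .training import LabeledDataset

N_AA = len(AMINO_ACIDS)


@dataclass
class SyntheticMsaSpec:
    """Alignment with i.i.d. background columns, planted covariation and
    conservation."""

    L: int
    M: int
    dirichlet_alpha: float = 1.0
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    planted_groups: list[tuple[list[int], float]] = field(default_factory=list)
    conserved_positions: list[tuple[int, float]] = field(default_factory=list)
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        used: set[int] = set()
        for i, j, rho in self.planted_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L) or i == j:
                raise ValueError(f"invalid planted pair ({i}, {j})")
            if {i, j} & used:
                raise ValueError("planted pairs must be disjoint")
            used |= {i, j}
            if not 0 <= rho <= 1:
                raise ValueError("coupling strength rho must lie in [0, 1]")
        for members, rho in self.planted_groups:
            if len(members) < 2 or len(set(members)) != len(members):
                raise ValueError("planted group needs >= 2 distinct members")
            if any(not 0 <= m < self.L for m in members):
                raise ValueError("planted group member out of range")
            if set(members) & used:
                raise ValueError("planted pairs/groups must be disjoint")
            used |= set(members)
            if not 0 <= rho <= 1:
                raise ValueError("coupling strength rho must lie in [0, 1]")
        for i, p in self.conserved_positions:
            if not 0 <= i < self.L:
                raise ValueError(f"conserved position {i} out of range")
            if not 0 <= p <= 1:
                raise ValueError("dominant-letter probability must lie in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")


def generate_msa(spec: SyntheticMsaSpec) -> MultipleSequenceAlignment:
    """Sample an alignment: background columns from per-column Dirichlet
    draws; each planted pair (i, j, ρ) copies a fixed bijective image of
    column i's letter into column j with probability ρ; each planted group
    couples all its members to one latent column through per-member
    bijections (a coevolving sector); conserved positions emit their
    dominant letter with the stated probability; gaps are i.i.d."""
    rng = np.random.default_rng(spec.seed)
    L, M = spec.L, spec.M
    col_dists = rng.dirichlet(np.full(N_AA, spec.dirichlet_alpha), size=L)
    for i, p in spec.conserved_positions:
        dominant = rng.integers(N_AA)
        dist = np.full(N_AA, (1.0 - p) / (N_AA - 1))
        dist[dominant] = p
        col_dists[i] = dist

    codes = np.empty((M, L), dtype=int)
    for i in range(L):
        codes[:, i] = rng.choice(N_AA, size=M, p=col_dists[i])
    for i, j, rho in spec.planted_pairs:
        bijection = rng.permutation(N_AA)
        copy = rng.random(M) < rho
        codes[copy, j] = bijection[codes[copy, i]]
    for members, rho in spec.planted_groups:
        latent = rng.choice(N_AA, size=M, p=col_dists[members[0]])
        for m in members:
            bijection = rng.permutation(N_AA)
            copy = rng.random(M) < rho
            codes[copy, m] = bijection[latent[copy]]

    letters = np.array(list(AMINO_ACIDS))
    rows_arr = letters[codes]
    if spec.gap_rate > 0:
        gaps = rng.random((M, L)) < spec.gap_rate
        rows_arr = np.where(gaps, GAP, rows_arr)
    rows = ["".join(r) for r in rows_arr]
    identifiers = [f"seq{i}" for i in range(M)]
    return MultipleSequenceAlignment(identifiers=identifiers, rows=rows)


@dataclass
class SyntheticFunctionSpec:
    """Labeled protein dataset with known functional sites.

    Each label owns ``sites_per_label`` designated residues and one
    permissive residue class of ``class_size`` letters (a coarse
    physicochemical class); the label fires iff every designated residue
    carries a letter of the class.  The rule is deliberately symmetric over
    the label's sites: graph convolution over the planted block then
    preserves its sufficient statistic (the within-block class count).  The
    designated residues are wired as a planted block (clique) in both
    channel adjacencies; sparse random background edges are drawn among the
    remaining residues so the planted communities stay exact.

    Node features are a seeded per-letter random projection concatenated
    with a sinusoidal positional channel — emulating the position-aware
    sequence embeddings the production pipeline consumes — scaled by
    ``feature_scale`` to keep the sum-pooled magnitudes moderate.
    """

    n_proteins: int = 2000
    length: int = 60
    n_labels: int = 4
    sites_per_label: int = 3
    class_size: int = 12
    feature_dim: int = 32
    position_dim: int = 8
    position_amplitude: float = 3.0
    feature_scale: float = 0.25
    noise_rate: float = 0.0
    background_edge_prob: float = 0.02
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labels * self.sites_per_label > self.length:
            raise ValueError("designated sites exceed protein length")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise rate must lie in [0, 0.5)")
        if not 1 <= self.class_size <= N_AA:
            raise ValueError("class_size must lie in [1, 20]")
        if not 0 <= self.position_dim < self.feature_dim:
            raise ValueError("position_dim must leave room for letter features")


def _motif_rules(spec: SyntheticFunctionSpec, rng: np.random.Generator):
    """Disjoint designated positions and one residue class per label."""
    positions = rng.permutation(spec.length)[: spec.n_labels * spec.sites_per_label]
    rules = []
    for c in range(spec.n_labels):
        sites = np.sort(
            positions[c * spec.sites_per_label : (c + 1) * spec.sites_per_label]
        )
        allowed = frozenset(rng.permutation(N_AA)[: spec.class_size].tolist())
        rules.append((sites, allowed))
    return rules


def generate_function_dataset(
    spec: SyntheticFunctionSpec,
) -> tuple[LabeledDataset, dict[tuple[int, int], list[int]]]:
    """Sample the dataset and its ground-truth site map.

    Returns the labeled dataset (train/validation/test splits assigned) and
    a map (protein index, label index) -> designated 1-based residue
    positions, recorded for every protein whose rule is causally satisfied.
    """
    rng = np.random.default_rng(spec.seed)
    rules = _motif_rules(spec, rng)

    # degenerate-class-balance guard on 1000 trial draws
    trial = rng.integers(N_AA, size=(1000, spec.length))
    for c, (sites, allowed) in enumerate(rules):
        sat = np.ones(1000, dtype=bool)
        for s in sites:
            sat &= np.isin(trial[:, s], list(allowed))
        rate = sat.mean()
        if not 0.05 <= rate <= 0.95:
            raise ValueError(
                f"label {c} satisfiable rate {rate:.3f} outside [0.05, 0.95]"
            )

    letters_arr = np.array(list(AMINO_ACIDS))
    letter_dim = spec.feature_dim - spec.position_dim
    feature_table = randproj_features(
        AMINO_ACIDS, D=letter_dim, seed=spec.seed
    ).values  # row per letter, fixed across proteins
    positional = (
        sinusoidal_positions(spec.length, spec.position_dim) * spec.position_amplitude
        if spec.position_dim
        else np.zeros((spec.length, 0))
    )

    motif_nodes = {int(s) for sites, _a in rules for s in sites}
    L = spec.length
    iu = np.triu_indices(L, k=1)
    bg_allowed = np.array(
        [i not in motif_nodes and j not in motif_nodes for i, j in zip(*iu)]
    )

    proteins: list[ProteinGraph] = []
    site_map: dict[tuple[int, int], list[int]] = {}
    for n in range(spec.n_proteins):
        codes = rng.integers(N_AA, size=L)
        labels = np.zeros(spec.n_labels)
        for c, (sites, allowed) in enumerate(rules):
            if all(codes[s] in allowed for s in sites):
                labels[c] = 1.0
                site_map[(n, c)] = [int(s) + 1 for s in sites]
        if spec.noise_rate > 0:
            flips = rng.random(spec.n_labels) < spec.noise_rate
            labels = np.abs(labels - flips)

        X = (
            np.concatenate([feature_table[codes], positional], axis=1)
            * spec.feature_scale
        )
        adjacencies = []
        for _channel in range(2):
            A = np.zeros((L, L))
            edges = (rng.random(len(iu[0])) < spec.background_edge_prob) & bg_allowed
            A[iu[0][edges], iu[1][edges]] = 1
            A = A + A.T
            for sites, _allowed in rules:
                for a in range(len(sites)):
                    for b in range(a + 1, len(sites)):
                        A[sites[a], sites[b]] = A[sites[b], sites[a]] = 1
            np.fill_diagonal(A, 0)
            adjacencies.append(A)
        proteins.append(
            ProteinGraph(
                features=X,
                adjacency_evc=adjacencies[0],
                adjacency_rc=adjacencies[1],
                labels=labels,
                protein_id=f"prot{n}",
                sequence="".join(letters_arr[codes]),
            )
        )

    order = rng.permutation(spec.n_proteins)
    n_train = int(round(spec.split_fractions[0] * spec.n_proteins))
    n_val = int(round(spec.split_fractions[1] * spec.n_proteins))
    splits = {
        "train": order[:n_train].tolist(),
        "validation": order[n_train : n_train + n_val].tolist(),
        "test": order[n_train + n_val :].tolist(),
    }
    vocabulary = [f"FUN:{c:04d}" for c in range(spec.n_labels)]
    dataset = LabeledDataset(proteins=proteins, vocabulary=vocabulary, splits=splits)
    return dataset, site_map


def generate_metric_fixture(
    N: int, F: int, quality: float, seed: int = 0, prevalence: float = 0.2
) -> EvaluationSet:
    """Prediction/truth fixture: truths ~ Bernoulli(prevalence); predictions
    blend truth with uniform noise, quality 1 giving a perfect predictor."""
    if not 0 <= quality <= 1:
        raise ValueError("quality must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truths = (rng.random((N, F)) < prevalence).astype(float)
    if truths.sum() < 1:
        truths[rng.integers(N), rng.integers(F)] = 1.0
    predictions = np.clip(
        quality * truths + (1.0 - quality) * rng.random((N, F)), 0.0, 1.0
    )
    return EvaluationSet(predictions=predictions, truths=truths)
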