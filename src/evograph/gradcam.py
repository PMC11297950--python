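"""Residue-level functional-importance scoring by gradient-weighted class
activation mapping.

The map is taken at the only residue-resolved layer of the network — the
L×2h concatenation of the two channel outputs, before sum pooling.  For a
function class c with predicted score Y^c, the neuron importances are
α_k^c = (1/L) Σ_i ∂Y^c/∂F_i^k and the raw residue score is
S^c(i) = ReLU(Σ_k α_k^c F^k(i)), normalized per protein to [0, 1].
Residues with normalized score ≥ 0.5 are called functional sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .graphnet import (
    ModelParameters,
    ProteinGraph,
    forward,
    relu,
    sigmoid,
    softmax,
)


@dataclass
class ActivationProfile:
    """Per-residue importance scores for one predicted function label."""

    scores: np.ndarray  # (L,) normalized to [0, 1]
    class_label: str
    raw_scores: np.ndarray  # (L,) pre-normalization, >= 0
    neuron_weights: np.ndarray  # (2h,) α_k^c

    @property
    def length(self) -> int:
        return len(self.scores)


def _head_gradient(
    fmap: np.ndarray, params: ModelParameters, class_index: int, use_logit: bool
) -> np.ndarray:
    """∂Y^c/∂F for the classification head; constant across residues since
    sum pooling is linear.  Returns the (2h,) per-feature gradient."""
    p = params.arrays
    pooled = fmap.sum(axis=0)
    Zf1 = pooled @ p["W_fc1"] + p["b_fc1"]
    Hf1 = relu(Zf1)
    logits = Hf1 @ p["W_fc2"] + p["b_fc2"]
    F = logits.shape[0]
    if params.config.get("output", "sigmoid") == "softmax":
        probs = softmax(logits)
        if use_logit:
            dlogits = np.eye(F)[class_index]
        else:
            dlogits = probs[class_index] * (np.eye(F)[class_index] - probs)
    else:
        if use_logit:
            dlogits = np.eye(F)[class_index]
        else:
            s = sigmoid(logits[class_index])
            dlogits = np.zeros(F)
            dlogits[class_index] = s * (1.0 - s)
    dHf1 = dlogits @ p["W_fc2"].T
    dZf1 = dHf1 * (Zf1 > 0)
    return p["W_fc1"] @ dZf1  # = ∂Y^c/∂pooled = ∂Y^c/∂F_i for every residue i


def activation_scores(
    params: ModelParameters,
    g: ProteinGraph,
    class_index: int,
    class_label: str | None = None,
    use_logit: bool = False,
) -> ActivationProfile:
    """Grad-CAM profile of one protein for one function class.

    ``use_logit`` switches the differentiated score Y^c from the post-sigmoid
    probability (default) to the pre-activation logit.
    """
    if not 0 <= class_index < params.n_classes:
        raise ValueError(
            f"class index {class_index} outside vocabulary of size {params.n_classes}"
        )
    result = forward(g, params, training_mode=False)
    fmap = result.pooled_feature_map  # (L, 2h)
    dpooled = _head_gradient(fmap, params, class_index, use_logit)
    alpha = dpooled  # mean over residues of a residue-constant gradient
    raw = relu(fmap @ alpha)
    peak = raw.max()
    scores = raw / peak if peak > 0 else raw.copy()
    return ActivationProfile(
        scores=scores,
        class_label=class_label if class_label is not None else str(class_index),
        raw_scores=raw,
        neuron_weights=alpha,
    )


def call_functional_sites(profile: ActivationProfile, cutoff: float = 0.5) -> list[int]:
    """Residues with normalized score >= cutoff, 1-based, sorted."""
    return [int(i) + 1 for i in np.flatnonzero(profile.scores >= cutoff)]


def site_agreement(
    profile: ActivationProfile,
    reference_sites: set[int] | list[int],
    cutoff: float = 0.5,
) -> dict[str, float]:
    """Compare a profile to curated reference sites (1-based residue indices).

    Returns AUROC of the scores against reference membership plus
    precision/recall of the called sites at ``cutoff``.
    """
    reference = {int(i) for i in reference_sites}
    if not reference:
        raise ValueError("reference site set must be nonempty")
    L = profile.length
    if any(i < 1 or i > L for i in reference):
        raise ValueError(f"reference indices out of range for protein of length {L}")
    truth = np.zeros(L)
    truth[[i - 1 for i in reference]] = 1
    if truth.all():
        auroc = float("nan")  # undefined without negatives
    else:
        auroc = float(roc_auc_score(truth, profile.scores))
    called = set(call_functional_sites(profile, cutoff))
    tp = len(called & reference)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(reference)
    return {"auroc": auroc, "precision": precision, "recall": recall}


def write_profile_tsv(
    profile: ActivationProfile,
    sequence: str,
    path: str | Path,
    cutoff: float = 0.5,
) -> None:
    """Write a profile as TSV: residue [1-based], amino acid, score, called."""
    called = set(call_functional_sites(profile, cutoff))
    with open(path, "w") as fh:
        fh.write("residue\tamino_acid\tscore\tcalled\n")
        for i, (aa, s) in enumerate(zip(sequence, profile.scores), start=1):
            fh.write(f"{i}\t{aa}\t{s:.6f}\t{1 if i in called else 0}\n")
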