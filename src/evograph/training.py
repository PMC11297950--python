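"""Multi-label training: BCE loss, Adam with decoupled weight decay,
minibatch loop with early stopping, and deterministic prediction.

The loss follows the mean-over-samples / sum-over-classes convention
L = −(1/N) Σ_i Σ_j [y_ij log ŷ_ij + (1−y_ij) log(1−ŷ_ij)].  Training uses
Adam (lr 2e-4, β1 0.9, β2 0.999, ε 1e-6) with L2 weight decay 2e-5 applied
decoupled to weight matrices (not biases), batch size 64, at most 500
epochs, early-stopped on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphnet import (
    ModelParameters,
    ProteinGraph,
    _backward_batch,
    _forward_batch,
    _stack_graphs,
    init_parameters,
)

_CLIP = 1e-7


@dataclass
class LabeledDataset:
    """Proteins with binary label vectors over a fixed function vocabulary."""

    proteins: list[ProteinGraph]
    vocabulary: list[str]
    splits: dict[str, list[int]] = field(default_factory=dict)  # tag -> indices

    def __post_init__(self) -> None:
        F = len(self.vocabulary)
        for g in self.proteins:
            if g.labels is None or len(np.asarray(g.labels)) != F:
                raise ValueError(
                    f"protein '{g.protein_id}' lacks a length-{F} label vector"
                )

    def subset(self, tag: str) -> list[ProteinGraph]:
        return [self.proteins[i] for i in self.splits.get(tag, [])]

    def labels(self, tag: str) -> np.ndarray:
        return np.stack([np.asarray(g.labels, dtype=float) for g in self.subset(tag)])


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-6
    weight_decay: float = 2e-5
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    dropout: float = 0.3
    seed: int = 0
    # optional convergence target: stop once validation loss drops below it
    target_validation_loss: float | None = None

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        for name in ("learning_rate", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def bce_loss(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Binary cross-entropy, mean over samples and sum over classes."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError(
            f"prediction shape {predictions.shape} != truth shape {truths.shape}"
        )
    p = np.clip(predictions, _CLIP, 1.0 - _CLIP)
    ll = truths * np.log(p) + (1.0 - truths) * np.log(1.0 - p)
    n = predictions.shape[0] if predictions.ndim > 1 else 1
    return float(-ll.sum() / n)


class _Adam:
    """Adam with decoupled L2 weight decay on weight matrices only."""

    def __init__(self, params: ModelParameters, tc: TrainConfig) -> None:
        self.tc = tc
        self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.t = 0

    def step(self, params: ModelParameters, grads: dict[str, np.ndarray]) -> None:
        tc = self.tc
        self.t += 1
        b1t = 1.0 - tc.beta1**self.t
        b2t = 1.0 - tc.beta2**self.t
        for k, w in params.arrays.items():
            g = grads[k]
            self.m[k] = tc.beta1 * self.m[k] + (1.0 - tc.beta1) * g
            self.v[k] = tc.beta2 * self.v[k] + (1.0 - tc.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + tc.eps)
            if k.startswith("W_") and tc.weight_decay > 0:
                update = update + tc.weight_decay * w
            w -= tc.learning_rate * update


def _prepare(graphs: list[ProteinGraph]):
    """Pre-normalize adjacencies and bucket proteins by length for stacking."""
    X, A_evc, A_rc = _stack_graphs(graphs)
    return X, A_evc, A_rc


def _group_by_length(indices: np.ndarray, lengths: np.ndarray) -> list[np.ndarray]:
    groups: dict[int, list[int]] = {}
    for i in indices:
        groups.setdefault(int(lengths[i]), []).append(int(i))
    return [np.array(v) for _, v in sorted(groups.items())]


def train(
    dataset: LabeledDataset,
    tc: TrainConfig | None = None,
    hidden: int = 512,
    output: str = "sigmoid",
    init: ModelParameters | None = None,
    verbose: bool = False,
) -> tuple[ModelParameters, pd.DataFrame]:
    """Fit the dual-channel network; returns the best-validation-loss
    parameters and a per-epoch loss log.

    Gradients of the mean-over-batch loss are accumulated over equal-length
    sub-stacks of each minibatch, which is numerically identical to
    per-protein accumulation.  Training arithmetic runs in float32 (the
    usual deep-learning precision; deterministic given ``tc.seed``), and
    the returned parameters are cast back to float64.
    """
    tc = tc or TrainConfig()
    train_graphs = dataset.subset("train")
    val_graphs = dataset.subset("validation")
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation splits must both be nonempty")

    F = len(dataset.vocabulary)
    D = train_graphs[0].feature_array.shape[1]
    if init is not None:
        params = init.copy()
    else:
        params = init_parameters(
            D, F, hidden=hidden, dropout=tc.dropout, output=output, seed=tc.seed
        )
        # start the output layer at zero: predictions open at the base rate,
        # which keeps the sum-pooled head out of sigmoid saturation
        params.arrays["W_fc2"][:] = 0.0
    params.config["dropout"] = tc.dropout
    params.arrays = {k: v.astype(np.float32) for k, v in params.arrays.items()}

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(params, tc)

    lengths = np.array([g.length for g in train_graphs])
    # cache normalized adjacencies/features per length bucket
    by_len: dict[int, tuple] = {}
    for Lval in sorted(set(lengths.tolist())):
        idx = np.where(lengths == Lval)[0]
        X, Ae, Ar = _prepare([train_graphs[i] for i in idx])
        Y = np.stack([np.asarray(train_graphs[i].labels, dtype=float) for i in idx])
        by_len[Lval] = (
            idx,
            X.astype(np.float32),
            Ae.astype(np.float32),
            Ar.astype(np.float32),
            Y,
        )
    pos_of = {}  # global index -> (bucket L, position)
    for Lval, (idx, *_rest) in by_len.items():
        for pos, i in enumerate(idx):
            pos_of[int(i)] = (Lval, pos)

    Xv, Aev, Arv = (
        a.astype(np.float32) for a in _prepare(val_graphs)
    )
    Yv = dataset.labels("validation")

    best_loss = np.inf
    best_params = params.copy()
    best_epoch = 0
    log_rows = []
    n_train = len(train_graphs)
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, tc.batch_size):
            batch = order[start : start + tc.batch_size]
            nb = len(batch)
            grads_sum: dict[str, np.ndarray] = {
                k: np.zeros_like(v) for k, v in params.arrays.items()
            }
            for grp in _group_by_length(batch, lengths):
                Lval = int(lengths[grp[0]])
                _, X, Ae, Ar, Y = by_len[Lval]
                pos = np.array([pos_of[int(i)][1] for i in grp])
                cache = _forward_batch(
                    X[pos], Ae[pos], Ar[pos], params, training=True, rng=rng
                )
                probs = np.clip(cache["probs"], _CLIP, 1.0 - _CLIP)
                y = Y[pos]
                epoch_loss += float(
                    -(y * np.log(probs) + (1 - y) * np.log(1 - probs)).sum()
                )
                # dL/dlogits of BCE-with-sigmoid, for the batch-mean loss
                dlogits = ((cache["probs"] - y) / nb).astype(np.float32)
                g = _backward_batch(params, cache, dlogits)
                for k in grads_sum:
                    grads_sum[k] += g[k]
            if any(not np.isfinite(v).all() for v in grads_sum.values()):
                raise RuntimeError(
                    f"divergent training: non-finite gradient at epoch {epoch}"
                )
            opt.step(params, grads_sum)
        train_loss = epoch_loss / n_train
        val_cache = _forward_batch(Xv, Aev, Arv, params, training=False)
        val_loss = bce_loss(val_cache["probs"], Yv)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise RuntimeError(f"divergent training: non-finite loss at epoch {epoch}")
        log_rows.append(
            {"epoch": epoch, "train_loss": train_loss, "validation_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch:4d}  train {train_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= tc.patience:
            break
        if (
            tc.target_validation_loss is not None
            and val_loss < tc.target_validation_loss
        ):
            break
    log = pd.DataFrame(log_rows)
    best_params.arrays = {
        k: v.astype(np.float64) for k, v in best_params.arrays.items()
    }
    return best_params, log


def predict(
    proteins: list[ProteinGraph],
    params: ModelParameters,
    vocabulary: list[str] | None = None,
) -> np.ndarray:
    """Deterministic N×F probability matrix (dropout disabled)."""
    if vocabulary is not None and len(vocabulary) != params.n_classes:
        raise ValueError(
            f"model predicts {params.n_classes} classes but vocabulary has "
            f"{len(vocabulary)} terms"
        )
    out = np.zeros((len(proteins), params.n_classes))
    lengths = np.array([g.length for g in proteins])
    for grp in _group_by_length(np.arange(len(proteins)), lengths):
        X, Ae, Ar = _prepare([proteins[i] for i in grp])
        cache = _forward_batch(X, Ae, Ar, params, training=False)
        out[grp] = cache["probs"]
    return out
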