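"""Dual-channel stacked graph convolutional network.

Two parallel stacks of three graph convolution layers read the same L×D
node features through two different residue graphs — one wired by
evolutionary couplings (EVC channel), one by residue communities (RC
channel).  Each layer applies the symmetric normalized propagation
H' = σ(D̂^{-1/2}(A+I)D̂^{-1/2} H W + b).  The channel outputs are
concatenated into the residue-resolved feature map F ∈ R^{L×2h} (the layer
class-activation mapping reads), sum-pooled over residues, and passed
through two fully connected layers (ReLU, then dropout) to per-class
sigmoid probabilities for multi-label function assignment.

All arithmetic is float64 NumPy with hand-written backward passes; given a
seed the model is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .couplings import BinaryAdjacency
from .features import NodeFeatureMatrix

CHANNELS = ("evc", "rc")
N_GCN_PER_CHANNEL = 3


class NumericalError(RuntimeError):
    """NaN/Inf encountered in a named layer."""


def _as_array(x) -> np.ndarray:
    if isinstance(x, NodeFeatureMatrix):
        return x.values
    if isinstance(x, BinaryAdjacency):
        return x.entries
    return np.asarray(x, dtype=float)


@dataclass
class ProteinGraph:
    """Node features plus the two channel adjacencies (and optional labels)."""

    features: NodeFeatureMatrix | np.ndarray
    adjacency_evc: BinaryAdjacency | np.ndarray
    adjacency_rc: BinaryAdjacency | np.ndarray
    labels: np.ndarray | None = None
    protein_id: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        X = _as_array(self.features)
        L = X.shape[0]
        for name in ("adjacency_evc", "adjacency_rc"):
            A = _as_array(getattr(self, name))
            if A.shape != (L, L):
                raise ValueError(f"{name} shape {A.shape} does not match L={L}")
            if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")

    @property
    def length(self) -> int:
        return _as_array(self.features).shape[0]

    @property
    def feature_array(self) -> np.ndarray:
        return _as_array(self.features)

    @property
    def evc_array(self) -> np.ndarray:
        return _as_array(self.adjacency_evc)

    @property
    def rc_array(self) -> np.ndarray:
        return _as_array(self.adjacency_rc)


@dataclass
class NormalizedAdjacency:
    """Â-normalized propagation operator D̂^{-1/2}(A+I)D̂^{-1/2}."""

    values: np.ndarray


def normalize_adjacency(A: BinaryAdjacency | np.ndarray) -> NormalizedAdjacency:
    """Symmetric renormalization with self-loops; never divides by zero since
    the self-loop guarantees degree >= 1."""
    A = _as_array(A)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    values = d_inv_sqrt[:, None] * A_hat * d_inv_sqrt[None, :]
    return NormalizedAdjacency(values=values)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gcn_layer(
    H: np.ndarray,
    A_norm: NormalizedAdjacency | np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None = None,
    activation=relu,
) -> np.ndarray:
    """One graph convolution: activation(A_norm · H · W + b)."""
    A = A_norm.values if isinstance(A_norm, NormalizedAdjacency) else np.asarray(A_norm)
    if H.shape[-1] != W.shape[0]:
        raise ValueError(f"feature dim {H.shape[-1]} does not match W rows {W.shape[0]}")
    Z = A @ H @ W
    if b is not None:
        Z = Z + b
    return activation(Z) if activation is not None else Z


@dataclass
class ModelParameters:
    """All weights of the dual-channel network plus its architecture config.

    config keys: input_dim, hidden, n_classes, dropout, output
    ("sigmoid" | "softmax"), seed.
    """

    arrays: dict[str, np.ndarray]
    config: dict = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            config=dict(self.config),
        )

    @property
    def n_classes(self) -> int:
        return self.arrays["W_fc2"].shape[1]

    @property
    def hidden(self) -> int:
        return self.arrays["W_evc1"].shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(
    input_dim: int,
    n_classes: int,
    hidden: int = 512,
    dropout: float = 0.3,
    output: str = "sigmoid",
    seed: int = 0,
) -> ModelParameters:
    """Seeded Glorot-uniform initialization; biases start at zero."""
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        dims = [input_dim] + [hidden] * N_GCN_PER_CHANNEL
        for k in range(N_GCN_PER_CHANNEL):
            arrays[f"W_{ch}{k + 1}"] = _glorot(rng, dims[k], dims[k + 1])
            arrays[f"b_{ch}{k + 1}"] = np.zeros(dims[k + 1])
    arrays["W_fc1"] = _glorot(rng, 2 * hidden, hidden)
    arrays["b_fc1"] = np.zeros(hidden)
    arrays["W_fc2"] = _glorot(rng, hidden, n_classes)
    arrays["b_fc2"] = np.zeros(n_classes)
    config = {
        "input_dim": input_dim,
        "hidden": hidden,
        "n_classes": n_classes,
        "dropout": dropout,
        "output": output,
        "seed": seed,
    }
    return ModelParameters(arrays=arrays, config=config)


@dataclass
class PredictionResult:
    """Class probabilities and the residue-resolved concatenated feature map."""

    probabilities: np.ndarray  # (F,) single protein, (N, F) batched
    pooled_feature_map: np.ndarray  # (L, 2h) or (N, L, 2h)


def _check_finite(name: str, x: np.ndarray) -> None:
    if not np.isfinite(x).all():
        raise NumericalError(f"non-finite values in {name}")


def _forward_batch(
    X: np.ndarray,  # (N, L, D)
    A_evc: np.ndarray,  # (N, L, L) normalized
    A_rc: np.ndarray,
    params: ModelParameters,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Batched forward pass; returns a cache holding every intermediate."""
    p = params.arrays
    cache: dict = {"X": X, "A": {"evc": A_evc, "rc": A_rc}, "H": {}, "training": training}
    outs = []
    for ch in CHANNELS:
        A = cache["A"][ch]
        H = X
        Hs = [H]
        for k in range(1, N_GCN_PER_CHANNEL + 1):
            Z = A @ H @ p[f"W_{ch}{k}"] + p[f"b_{ch}{k}"]
            H = relu(Z)
            _check_finite(f"gcn {ch}{k}", H)
            Hs.append(H)
        cache["H"][ch] = Hs
        outs.append(H)
    fmap = np.concatenate(outs, axis=-1)  # (N, L, 2h)
    pooled = fmap.sum(axis=-2)  # (N, 2h)
    Zf1 = pooled @ p["W_fc1"] + p["b_fc1"]
    Hf1 = relu(Zf1)
    _check_finite("fc1", Hf1)
    dropout = float(params.config.get("dropout", 0.0))
    if training and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (
            (rng.random(Hf1.shape) >= dropout) / (1.0 - dropout)
        ).astype(Hf1.dtype)
    else:
        mask = np.ones_like(Hf1)
    Hf1d = Hf1 * mask
    logits = Hf1d @ p["W_fc2"] + p["b_fc2"]
    _check_finite("fc2", logits)
    if params.config.get("output", "sigmoid") == "softmax":
        probs = softmax(logits)
    else:
        probs = sigmoid(logits)
    cache.update(
        fmap=fmap, pooled=pooled, Zf1=Zf1, Hf1=Hf1, mask=mask, Hf1d=Hf1d,
        logits=logits, probs=probs,
    )
    return cache


def _backward_batch(params: ModelParameters, cache: dict, dlogits: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. all parameters, given dL/dlogits.

    Sums over the batch; the caller owns any 1/N normalization.
    """
    p = params.arrays
    grads: dict[str, np.ndarray] = {}
    grads["W_fc2"] = cache["Hf1d"].reshape(-1, p["W_fc2"].shape[0]).T @ dlogits.reshape(
        -1, p["W_fc2"].shape[1]
    )
    grads["b_fc2"] = dlogits.sum(axis=tuple(range(dlogits.ndim - 1)))
    dHf1d = dlogits @ p["W_fc2"].T
    dHf1 = dHf1d * cache["mask"]
    dZf1 = dHf1 * (cache["Zf1"] > 0)
    grads["W_fc1"] = cache["pooled"].reshape(-1, p["W_fc1"].shape[0]).T @ dZf1.reshape(
        -1, p["W_fc1"].shape[1]
    )
    grads["b_fc1"] = dZf1.sum(axis=tuple(range(dZf1.ndim - 1)))
    dpooled = dZf1 @ p["W_fc1"].T  # (N, 2h)
    dfmap = np.repeat(dpooled[..., None, :], cache["fmap"].shape[-2], axis=-2)
    h = params.hidden
    for idx, ch in enumerate(CHANNELS):
        dH = dfmap[..., idx * h : (idx + 1) * h]
        A = cache["A"][ch]
        Hs = cache["H"][ch]
        for k in range(N_GCN_PER_CHANNEL, 0, -1):
            dZ = dH * (Hs[k] > 0)
            AH = A @ Hs[k - 1]  # (N, L, d_in)
            W = p[f"W_{ch}{k}"]
            grads[f"W_{ch}{k}"] = np.einsum("nld,nle->de", AH, dZ)
            grads[f"b_{ch}{k}"] = dZ.sum(axis=(0, 1))
            if k > 1:
                dH = A @ (dZ @ W.T)  # A symmetric
    return grads


def _stack_graphs(graphs: list[ProteinGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([g.feature_array for g in graphs])
    A_evc = np.stack([normalize_adjacency(g.evc_array).values for g in graphs])
    A_rc = np.stack([normalize_adjacency(g.rc_array).values for g in graphs])
    return X, A_evc, A_rc


def forward(
    g: ProteinGraph,
    params: ModelParameters,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Full forward pass for one protein."""
    X, A_evc, A_rc = _stack_graphs([g])
    cache = _forward_batch(X, A_evc, A_rc, params, training=training_mode, rng=rng)
    return PredictionResult(
        probabilities=cache["probs"][0], pooled_feature_map=cache["fmap"][0]
    )


def head_forward(fmap: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Classification head only (pool → FC1 → FC2 → output), evaluation mode.

    Takes the residue-resolved feature map F (L×2h) and returns class
    probabilities; this is the function class-activation mapping
    differentiates.
    """
    p = params.arrays
    pooled = fmap.sum(axis=-2)
    Hf1 = relu(pooled @ p["W_fc1"] + p["b_fc1"])
    logits = Hf1 @ p["W_fc2"] + p["b_fc2"]
    if params.config.get("output", "sigmoid") == "softmax":
        return softmax(logits)
    return sigmoid(logits)


def save_model(params: ModelParameters, path: str | Path) -> None:
    """Serialize parameters to a single .npz archive with a JSON manifest."""
    manifest = {
        "config": params.config,
        "shapes": {k: list(v.shape) for k, v in params.arrays.items()},
        "format_version": 1,
    }
    np.savez(path, __manifest__=np.array(json.dumps(manifest)), **params.arrays)


def load_model(path: str | Path) -> ModelParameters:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["__manifest__"]))
        arrays = {k: data[k] for k in data.files if k != "__manifest__"}
    return ModelParameters(arrays=arrays, config=manifest["config"])
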