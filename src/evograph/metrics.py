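"""CAFA-style evaluation: protein-centric F_max, term-centric AUPR,
Matthews correlation, bootstrap summaries, and identity-stratified slices.

F_max sweeps a threshold grid; at each t, precision averages TP/predicted
over proteins that predict at least one term at t (the CAFA convention) and
recall averages TP/true over proteins with at least one true term.  AUPR is
the per-term area under the precision–recall curve (step interpolation),
macro-averaged over terms with positives; a literal threshold integral
∫ p(t)·r(t) dt is available for comparison.  MCC pools the binary confusion
counts over all (protein, term) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score


@dataclass
class EvaluationSet:
    """Prediction scores vs binary truths over a protein × term grid."""

    predictions: np.ndarray  # (N, F) in [0, 1]
    truths: np.ndarray  # (N, F) binary
    vocabulary: list[str] | None = None
    identities: np.ndarray | None = None  # per-protein max identity to training

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.truths = np.asarray(self.truths, dtype=float)
        if self.predictions.shape != self.truths.shape:
            raise ValueError("predictions and truths must share shape (N, F)")
        if self.truths.sum() < 1:
            raise ValueError("evaluation set needs at least one positive truth")
        if self.identities is not None:
            ident = np.asarray(self.identities, dtype=float)
            if ident.min() < 0 or ident.max() > 1:
                raise ValueError("identities must lie in [0, 1]")
            self.identities = ident

    @property
    def n_proteins(self) -> int:
        return self.predictions.shape[0]

    def subset(self, rows: np.ndarray) -> "EvaluationSet":
        return EvaluationSet(
            predictions=self.predictions[rows],
            truths=self.truths[rows],
            vocabulary=self.vocabulary,
            identities=None if self.identities is None else self.identities[rows],
        )


def fmax(ev: EvaluationSet, grid_step: float = 0.01) -> dict[str, float]:
    """Protein-centric F_max over a threshold grid.

    Returns F_max, the maximizing threshold, and precision/recall there.
    """
    y, p = ev.truths, ev.predictions
    has_truth = y.sum(axis=1) > 0
    if not has_truth.any():
        raise ValueError("no protein has a true label")
    thresholds = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    best = {"fmax": 0.0, "threshold": 0.0, "precision": 0.0, "recall": 0.0}
    for t in thresholds:
        pred_pos = p >= t
        n_pred = pred_pos.sum(axis=1)
        tp = (pred_pos & (y > 0)).sum(axis=1)
        covered = n_pred > 0
        prec = float((tp[covered] / n_pred[covered]).mean()) if covered.any() else 0.0
        rec = float((tp[has_truth] / y[has_truth].sum(axis=1)).mean())
        f = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        if f > best["fmax"]:
            best = {"fmax": f, "threshold": float(t), "precision": prec, "recall": rec}
    return best


def aupr(ev: EvaluationSet, averaging: str = "macro_term", method: str = "pr_curve") -> float:
    """Term-centric area under the precision–recall curve.

    averaging
        ``macro_term`` averages per-term AUPR over terms with at least one
        positive (terms without positives are skipped); ``micro`` pools all
        (protein, term) pairs into one curve.
    method
        ``pr_curve`` (default) is the standard step-interpolated area;
        ``threshold_integral`` evaluates the literal integral
        ∫₀¹ p(t)·r(t) dt on the pooled pairs over a 0.01 threshold grid.
    """
    y, p = ev.truths, ev.predictions
    if method == "threshold_integral":
        ts = np.arange(0.0, 1.0 + 0.005, 0.01)
        vals = []
        yf, pf = y.ravel(), p.ravel()
        for t in ts:
            pred = pf >= t
            tp = float((pred & (yf > 0)).sum())
            prec = tp / pred.sum() if pred.any() else 1.0
            rec = tp / yf.sum()
            vals.append(prec * rec)
        return float(np.trapezoid(vals, ts))
    if method != "pr_curve":
        raise ValueError(f"unknown AUPR method '{method}'")
    if averaging == "micro":
        return float(average_precision_score(y.ravel(), p.ravel()))
    if averaging != "macro_term":
        raise ValueError(f"unknown averaging '{averaging}'")
    vals = []
    for j in range(y.shape[1]):
        if y[:, j].sum() > 0:
            vals.append(float(average_precision_score(y[:, j], p[:, j])))
    return float(np.mean(vals))


def mcc(
    predictions: np.ndarray, truths: np.ndarray, cutoff: float = 0.5
) -> float:
    """Matthews correlation coefficient over pooled confusion counts.

    ``predictions`` may be scores (binarized at ``cutoff``) or already binary.
    A zero denominator yields 0.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must share shape")
    pred = predictions >= cutoff
    truth = truths > 0
    tp = float((pred & truth).sum())
    tn = float((~pred & ~truth).sum())
    fp = float((pred & ~truth).sum())
    fn = float((~pred & truth).sum())
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def bootstrap(
    ev: EvaluationSet, metric, n_boot: int, seed: int = 0
) -> dict[str, object]:
    """Resample proteins with replacement and recompute a metric.

    ``metric`` maps an EvaluationSet to a float.  Replicates whose resample
    has no positive truth are redrawn (degenerate for every metric here).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    values = []
    n = ev.n_proteins
    while len(values) < n_boot:
        rows = rng.integers(0, n, size=n)
        if ev.truths[rows].sum() < 1:
            continue
        values.append(float(metric(ev.subset(rows))))
    values = np.array(values)
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "values": values,
    }


def identity_stratified(
    ev: EvaluationSet,
    metric,
    thresholds: list[float] = (0.30, 0.40, 0.50, 0.70, 0.95),
) -> dict[float, float | None]:
    """Evaluate a metric on proteins with identity-to-training <= each threshold.

    Empty strata are reported as None (missing).
    """
    if ev.identities is None:
        raise ValueError("evaluation set carries no per-protein identity values")
    out: dict[float, float | None] = {}
    for tau in thresholds:
        rows = np.flatnonzero(ev.identities <= tau)
        if rows.size == 0 or ev.truths[rows].sum() < 1:
            out[float(tau)] = None
        else:
            out[float(tau)] = float(metric(ev.subset(rows)))
    return out
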