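"""Evaluation metrics against independent brute-force implementations."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from evograph.metrics import (
    EvaluationSet,
    aupr,
    bootstrap,
    fmax,
    identity_stratified,
    mcc,
)
from evograph.synthetic import generate_metric_fixture


def fmax_bruteforce(pred, truth, step=0.01):
    """Independent loop implementation of the protein-centric F_max scan."""
    best = 0.0
    t = 0.0
    while t <= 1.0 + 1e-9:
        precisions, recalls = [], []
        for i in range(pred.shape[0]):
            called = [j for j in range(pred.shape[1]) if pred[i, j] >= t]
            true = [j for j in range(pred.shape[1]) if truth[i, j] > 0]
            tp = len(set(called) & set(true))
            if called:
                precisions.append(tp / len(called))
            if true:
                recalls.append(tp / len(true))
        p = sum(precisions) / len(precisions) if precisions else 0.0
        r = sum(recalls) / len(recalls) if recalls else 0.0
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
        t += step
    return best


def aupr_bruteforce(scores, truth):
    """Step-interpolated area under the PR curve at every distinct score."""
    order = np.argsort(-scores, kind="stable")
    y = truth[order]
    tp = np.cumsum(y)
    prec = tp / np.arange(1, len(y) + 1)
    rec = tp / y.sum()
    area, prev_r = 0.0, 0.0
    for p_i, r_i, y_i in zip(prec, rec, y):
        if y_i:
            area += (r_i - prev_r) * p_i
            prev_r = r_i
    return area


class TestFmax:
    def test_perfect_predictor(self):
        ev = generate_metric_fixture(N=30, F=5, quality=1.0, seed=0)
        assert fmax(ev)["fmax"] == pytest.approx(1.0)

    def test_all_zero_predictions(self):
        truths = np.zeros((4, 3))
        truths[0, 0] = 1
        ev = EvaluationSet(predictions=np.zeros((4, 3)), truths=truths)
        # at t=0 every term is called for every protein; F is prevalence-like,
        # and the scan never exceeds the all-called operating point
        res = fmax(ev)
        assert res["fmax"] == fmax_bruteforce(ev.predictions, ev.truths)

    def test_small_case_matches_bruteforce(self):
        truths = np.array([[1, 0], [1, 1]], dtype=float)
        preds = np.array([[0.9, 0.6], [0.8, 0.1]])
        ev = EvaluationSet(predictions=preds, truths=truths)
        assert fmax(ev)["fmax"] == pytest.approx(
            fmax_bruteforce(preds, truths), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixtures_match_bruteforce(self, seed):
        ev = generate_metric_fixture(N=12, F=4, quality=0.5, seed=seed)
        assert fmax(ev)["fmax"] == pytest.approx(
            fmax_bruteforce(ev.predictions, ev.truths), abs=1e-12
        )

    def test_no_positive_truth_errors(self):
        with pytest.raises(ValueError):
            EvaluationSet(predictions=np.ones((2, 2)), truths=np.zeros((2, 2)))


class TestAupr:
    def test_perfect_scores(self):
        ev = generate_metric_fixture(N=40, F=4, quality=1.0, seed=1)
        assert aupr(ev) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        ev = generate_metric_fixture(N=4000, F=3, quality=0.0, seed=2)
        assert aupr(ev, averaging="micro") == pytest.approx(0.2, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_per_term(self, seed):
        ev = generate_metric_fixture(N=15, F=3, quality=0.4, seed=seed)
        expected = np.mean(
            [
                aupr_bruteforce(ev.predictions[:, j], ev.truths[:, j])
                for j in range(3)
                if ev.truths[:, j].sum() > 0
            ]
        )
        assert aupr(ev) == pytest.approx(expected, abs=1e-12)

    def test_protein_order_invariance(self):
        ev = generate_metric_fixture(N=25, F=3, quality=0.5, seed=3)
        perm = np.random.default_rng(0).permutation(25)
        assert aupr(ev) == pytest.approx(aupr(ev.subset(perm)))

    def test_literal_threshold_integral_differs_but_bounded(self):
        ev = generate_metric_fixture(N=50, F=3, quality=0.8, seed=4)
        lit = aupr(ev, method="threshold_integral")
        assert 0.0 <= lit <= 1.0


class TestMcc:
    def test_perfect_and_inverted(self):
        truths = np.array([[1, 0, 1], [0, 1, 0]], dtype=float)
        assert mcc(truths, truths) == pytest.approx(1.0)
        assert mcc(1 - truths, truths) == pytest.approx(-1.0)

    def test_hand_counts(self):
        # TP=6, TN=3, FP=1, FN=2 -> (18-2)/sqrt(7*8*4*5)
        pred = np.array([1] * 6 + [0] * 3 + [1] + [0] * 2, dtype=float)
        truth = np.array([1] * 6 + [0] * 3 + [0] + [1] * 2, dtype=float)
        assert mcc(pred, truth) == pytest.approx(16 / np.sqrt(7 * 8 * 4 * 5))

    def test_matches_sklearn_pooled(self):
        ev = generate_metric_fixture(N=40, F=4, quality=0.6, seed=5)
        pred = (ev.predictions >= 0.5).astype(int).ravel()
        assert mcc(ev.predictions, ev.truths) == pytest.approx(
            matthews_corrcoef(ev.truths.ravel().astype(int), pred)
        )

    def test_zero_denominator_is_zero(self):
        assert mcc(np.ones((2, 2)), np.ones((2, 2))) == 0.0

    def test_symmetric_under_joint_inversion(self):
        ev = generate_metric_fixture(N=30, F=3, quality=0.5, seed=6)
        a = mcc(ev.predictions, ev.truths)
        b = mcc(1 - ev.predictions - 1e-9, 1 - ev.truths)
        assert a == pytest.approx(b, abs=1e-9)


class TestBootstrap:
    def test_constant_metric_zero_sd(self):
        ev = generate_metric_fixture(N=30, F=4, quality=1.0, seed=7)
        out = bootstrap(ev, lambda e: fmax(e)["fmax"], n_boot=10, seed=1)
        assert out["sd"] == pytest.approx(0.0)
        assert out["mean"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_boot", [10, 50])
    def test_seeded_reproducibility(self, n_boot):
        ev = generate_metric_fixture(N=25, F=3, quality=0.5, seed=8)
        metric = lambda e: aupr(e)
        a = bootstrap(ev, metric, n_boot=n_boot, seed=42)
        b = bootstrap(ev, metric, n_boot=n_boot, seed=42)
        assert np.array_equal(a["values"], b["values"])
        assert len(a["values"]) == n_boot

    def test_mean_within_replicate_range(self):
        ev = generate_metric_fixture(N=25, F=3, quality=0.5, seed=9)
        out = bootstrap(ev, lambda e: fmax(e)["fmax"], n_boot=10, seed=3)
        assert out["values"].min() <= out["mean"] <= out["values"].max()


class TestIdentityStratified:
    def test_uniform_identities_match_full_metric(self):
        ev = generate_metric_fixture(N=20, F=3, quality=0.7, seed=10)
        ev.identities = np.full(20, 0.2)
        strat = identity_stratified(ev, lambda e: fmax(e)["fmax"])
        full = fmax(ev)["fmax"]
        assert all(v == pytest.approx(full) for v in strat.values())

    def test_thresholds_below_min_identity_missing(self):
        ev = generate_metric_fixture(N=20, F=3, quality=0.7, seed=11)
        ev.identities = np.full(20, 0.99)
        strat = identity_stratified(ev, lambda e: fmax(e)["fmax"])
        assert all(v is None for v in strat.values())

    def test_two_strata_match_subset_oracle(self):
        ev = generate_metric_fixture(N=40, F=3, quality=0.6, seed=12)
        ident = np.array([0.25] * 20 + [0.9] * 20)
        ev.identities = ident
        metric = lambda e: fmax(e)["fmax"]
        strat = identity_stratified(ev, metric, thresholds=[0.30, 0.95])
        assert strat[0.30] == pytest.approx(metric(ev.subset(np.arange(20))))
        assert strat[0.95] == pytest.approx(metric(ev))

    def test_invalid_identities_rejected(self):
        ev = generate_metric_fixture(N=5, F=2, quality=0.5, seed=13)
        with pytest.raises(ValueError):
            ev.identities = np.array([0.1, 0.2, 1.5, 0.3, 0.4])
            EvaluationSet(
                predictions=ev.predictions,
                truths=ev.truths,
                identities=ev.identities,
            )
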