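"""AUC, DeLong inference, Youden thresholds, confusion metrics, DCA."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from habitatpipe.metrics import (
    confusion_from_counts,
    confusion_metrics,
    dca_net_benefit,
    delong_ci,
    delong_paired_test,
    delong_variance,
    emit_report,
    roc_auc,
    youden_threshold,
)


def _auc_pairs(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.full(10, 0.5), np.array([1] * 4 + [0] * 6)) == 0.5

    def test_eight_hand_scores_vs_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.7, 0.2, 0.5])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        assert roc_auc(scores, labels) == pytest.approx(_auc_pairs(scores, labels), abs=1e-15)

    def test_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(_auc_pairs(scores, labels), abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def _placement_oracle(scores, labels):
    """Direct double-loop structural components of the DeLong variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((n < pos) + 0.5 * (n == pos)) for n in neg])
    m, n = len(pos), len(neg)
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:3] = 1
        y[-3:] = 0
        assert delong_paired_test(s, s, y) == 1.0

    def test_variance_matches_direct_oracle_on_toy(self):
        scores = np.array([0.1, 0.2, 0.3, 0.35, 0.4, 0.5, 0.55, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1])
        auc, var = delong_variance(scores, labels)
        assert auc == pytest.approx(_auc_pairs(scores, labels))
        assert var == pytest.approx(_placement_oracle(scores, labels), abs=1e-12)

    def test_ci_brackets_auc_and_truncates(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(size=60) > 0).astype(int)
        lo, hi = delong_ci(scores, labels)
        auc = roc_auc(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_null_type_one_error_calibrated(self):
        # two uninformative models, paired: rejection rate should be ~ alpha
        rng = np.random.default_rng(3)
        n, reps = 1000, 500
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        rejections = 0
        for _ in range(reps):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            rejections += delong_paired_test(a, b, labels) < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_ci_coverage_at_known_auc(self):
        # binormal model with true AUC 0.75 at n = 100 per cohort
        from scipy.stats import norm

        rng = np.random.default_rng(4)
        mu = np.sqrt(2) * norm.ppf(0.75)
        reps, covered = 500, 0
        labels = np.array([1] * 50 + [0] * 50)
        for _ in range(reps):
            scores = np.concatenate([rng.normal(mu, 1, 50), rng.normal(0, 1, 50)])
            lo, hi = delong_ci(scores, labels)
            covered += lo <= 0.75 <= hi
        assert 0.92 <= covered / reps <= 0.98


class TestYouden:
    def test_separable_returns_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert youden_threshold(scores, labels) == pytest.approx(0.5)

    def test_all_equal_warns_and_returns_score(self):
        with pytest.warns(UserWarning, match="identical"):
            t = youden_threshold(np.full(8, 0.4), np.array([1, 0] * 4))
        assert t == 0.4

    def test_matches_exhaustive_cutpoint_search(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.random(10), 2)
        labels = rng.integers(0, 2, size=10)
        labels[0], labels[1] = 1, 0
        t = youden_threshold(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]

        def j_at(cut):
            return (pos >= cut).mean() + (neg < cut).mean() - 1

        assert j_at(t) == pytest.approx(max(j_at(c) for c in np.unique(scores)), abs=1e-12)

    def test_threshold_application_is_split_honest(self):
        rng = np.random.default_rng(6)
        train_scores = rng.random(50)
        train_labels = (train_scores + rng.normal(0, 0.3, 50) > 0.5).astype(int)
        train_labels[:2] = [0, 1]
        t = youden_threshold(train_scores, train_labels)
        test_scores = rng.random(30)
        m = confusion_metrics(test_scores, (test_scores > 0.5).astype(int), t)
        recomputed = confusion_metrics(test_scores, (test_scores > 0.5).astype(int), t)
        assert m == recomputed


class TestConfusionMetrics:
    def test_printed_cohort_counts_reproduce_reported_metrics(self):
        # 54-case cohort, 18 positives: TP=13 FN=5 TN=22 FP=14
        m = confusion_from_counts(tp=13, fp=14, tn=22, fn=5)
        assert m["accuracy"] == pytest.approx(0.648, abs=5e-4)
        assert m["ppv"] == pytest.approx(0.481, abs=5e-4)
        assert m["npv"] == pytest.approx(0.815, abs=5e-4)

    def test_all_predicted_positive(self):
        scores = np.full(20, 0.9)
        labels = np.array([1] * 6 + [0] * 14)
        m = confusion_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["ppv"] == pytest.approx(6 / 20)

    def test_counts_and_scores_paths_agree(self):
        rng = np.random.default_rng(7)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        t = 0.5
        pred = scores >= t
        m1 = confusion_metrics(scores, labels, t)
        m2 = confusion_from_counts(
            tp=int(np.sum(pred & (labels == 1))),
            fp=int(np.sum(pred & (labels == 0))),
            tn=int(np.sum(~pred & (labels == 0))),
            fn=int(np.sum(~pred & (labels == 1))),
        )
        assert m1 == m2

    def test_zero_denominator_flagged_as_zero(self):
        m = confusion_from_counts(tp=0, fp=0, tn=10, fn=5)
        assert m["ppv"] == 0.0


class TestDCA:
    def test_treat_all_approaches_prevalence(self):
        labels = np.array([1] * 3 + [0] * 7)
        curve = dca_net_benefit(np.linspace(0, 1, 10), labels, grid=np.array([0.01]))
        assert curve.treat_all[0] == pytest.approx(0.3 - 0.7 * 0.01 / 0.99)

    def test_perfect_probabilities_net_benefit_equals_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0])
        curve = dca_net_benefit(labels.astype(float), labels)
        assert np.allclose(curve.net_benefit, 0.4)

    def test_matches_enumeration_on_twenty_cases(self):
        rng = np.random.default_rng(8)
        p = rng.random(20)
        y = rng.integers(0, 2, size=20)
        grid = np.arange(0.05, 1.0, 0.05)
        curve = dca_net_benefit(p, y, grid=grid)
        for i, pt in enumerate(grid):
            tp = sum(1 for pi, yi in zip(p, y) if pi >= pt and yi == 1)
            fp = sum(1 for pi, yi in zip(p, y) if pi >= pt and yi == 0)
            assert curve.net_benefit[i] == pytest.approx(tp / 20 - fp / 20 * pt / (1 - pt), abs=1e-12)

    def test_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        y = rng.integers(0, 2, size=200)
        curve = dca_net_benefit(p, y)
        assert np.all(curve.net_benefit <= y.mean() + 1e-12)

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        curve = dca_net_benefit(np.linspace(0, 1, 100), y, grid=np.array([0.299, 0.3, 0.301]))
        assert curve.treat_all[1] == pytest.approx(0.0, abs=1e-12)
        assert curve.treat_all[0] > 0 > curve.treat_all[2]

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            dca_net_benefit(np.array([0.5]), np.array([1]), grid=np.array([0.0, 0.5]))


class TestEmitReport:
    def test_shape_and_round_trip_consistency(self):
        rng = np.random.default_rng(10)
        model_scores = {}
        for mid in ("A", "B", "C", "D", "E"):
            scores = {}
            for split, n in (("train", 60), ("test", 30)):
                y = rng.integers(0, 2, size=n)
                y[:2] = [0, 1]
                s = np.clip(0.5 * y + rng.normal(0.3, 0.2, n), 0, 1)
                scores[split] = (s, y)
            model_scores[mid] = scores
        thresholds = {m: 0.5 for m in model_scores}
        rep = emit_report(model_scores, thresholds)
        assert len(rep["table"]) == 10
        row = rep["table"].set_index(["model", "split"]).loc[("A", "test")]
        s, y = model_scores["A"]["test"]
        assert row["auc"] == pytest.approx(roc_auc(s, y))
        assert row["accuracy"] == pytest.approx(confusion_metrics(s, y, 0.5)["accuracy"])
        mat = rep["delong"]["test"]
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.all(np.diag(mat.to_numpy()) == 1.0)
        assert set(rep["dca"]) == set(model_scores)
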