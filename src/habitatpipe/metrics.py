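"""ROC/AUC with DeLong inference, Youden thresholds, confusion metrics,
and decision-curve net benefit.

AUC is the Mann-Whitney statistic (ties count 1/2). DeLong variance uses
the placement-value (structural component) estimator; confidence
intervals are normal-approximation on the AUC scale, truncated to
[0, 1]; the paired test is a two-sided normal test on the AUC difference
with the placement covariance. Classification uses "score >= threshold
-> predict positive"; undefined ratios from empty denominators are
reported as 0 and flagged. Net benefit follows
NB(pt) = TP/n - (FP/n) * pt / (1 - pt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def _split_scores(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = U / (n1 n0), ties counted one half."""
    pos, neg = _split_scores(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, var(AUC)) by the DeLong structural-component estimator."""
    auc, v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the AUC, truncated to [0, 1]."""
    auc, var = delong_variance(scores, labels)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> float:
    """Two-sided DeLong test for a difference in correlated AUCs."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must cover the same cases")
    if np.array_equal(scores_a, scores_b):
        return 1.0
    auc_a, v10a, v01a = _placements(scores_a, labels)
    auc_b, v10b, v01b = _placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ s @ contrast)
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 1.0
        raise ValueError("degenerate zero variance with unequal AUCs")
    z = diff / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def youden_threshold(train_scores: np.ndarray, train_labels: np.ndarray) -> float:
    """Maximize J = sensitivity + specificity - 1 over observed cut-points.

    Candidates are the observed scores (predict positive iff score >=
    t). Ties prefer higher specificity, then the lower cut-point. The
    returned threshold is the midpoint between the winning cut-point and
    the next lower observed score (same classification, centered in the
    gap); with all scores equal the common score is returned with a
    warning.
    """
    scores = np.asarray(train_scores, float)
    pos, neg = _split_scores(scores, train_labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        warnings.warn("all scores identical: Youden index is 0 everywhere", stacklevel=2)
        return float(uniq[0])
    best = None  # (J, spec, -t, t_index)
    for i, t in enumerate(uniq):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        key = (j, spec, -t)
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    if i == 0:
        return float(uniq[0])
    return float(0.5 * (uniq[i] + uniq[i - 1]))


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: list[str] = field(default_factory=list)

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            self.undefined.append(name)
            return 0.0
        return num / den

    def as_dict(self) -> dict[str, float]:
        self.undefined = []
        n = self.tp + self.fp + self.tn + self.fn
        return {
            "accuracy": self._ratio(self.tp + self.tn, n, "accuracy"),
            "sensitivity": self._ratio(self.tp, self.tp + self.fn, "sensitivity"),
            "specificity": self._ratio(self.tn, self.tn + self.fp, "specificity"),
            "ppv": self._ratio(self.tp, self.tp + self.fp, "ppv"),
            "npv": self._ratio(self.tn, self.tn + self.fn, "npv"),
            "f1": self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn, "f1"),
        }


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV/F1 from raw counts."""
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn).as_dict()


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict[str, float]:
    """Threshold a score vector (>= t positive) and compute the metric set."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return confusion_from_counts(tp, fp, tn, fn)


@dataclass
class DCACurve:
    """Net benefit across threshold probabilities, with reference policies."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )


def dca_net_benefit(probabilities: np.ndarray, labels: np.ndarray, grid: np.ndarray | None = None) -> DCACurve:
    """Decision-curve net benefit NB(pt) = TP/n - (FP/n) pt/(1-pt).

    Positives are cases with predicted probability >= pt. The treat-all
    policy has NB = pi - (1 - pi) pt/(1 - pt); treat-none is zero.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
    grid = np.asarray(grid, float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = y.size
    pi = y.mean()
    odds = grid / (1 - grid)
    nb = np.empty_like(grid)
    for i, pt in enumerate(grid):
        pred = p >= pt
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        nb[i] = tp / n - (fp / n) * odds[i]
    return DCACurve(
        thresholds=grid,
        net_benefit=nb,
        treat_all=pi - (1 - pi) * odds,
        treat_none=np.zeros_like(grid),
        prevalence=float(pi),
    )


def evaluation_row(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict[str, float]:
    """One report row: AUC with CI plus thresholded confusion metrics."""
    auc = roc_auc(scores, labels)
    lo, hi = delong_ci(scores, labels)
    row = {"auc": auc, "auc_ci_low": lo, "auc_ci_high": hi, "threshold": threshold}
    row.update(confusion_metrics(scores, labels, threshold))
    return row


def emit_report(
    model_scores: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
    thresholds: dict[str, float],
    dca_split: str = "test",
) -> dict:
    """Table-shaped evaluation report over models x splits.

    ``model_scores[model][split] = (probabilities, labels)``; the
    training Youden threshold of each model is applied to both splits
    (split-honest). Returns the metric table, the pairwise DeLong
    p-value matrix per split, and DCA curves for ``dca_split``.
    """
    rows = []
    for model, splits in model_scores.items():
        for split, (scores, labels) in splits.items():
            row = {"model": model, "split": split}
            row.update(evaluation_row(scores, labels, thresholds[model]))
            rows.append(row)
    table = pd.DataFrame(rows)

    models = list(model_scores)
    delong = {}
    for split in next(iter(model_scores.values())):
        mat = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
        for i, a in enumerate(models):
            for b in models[i + 1 :]:
                sa, la = model_scores[a][split]
                sb, lb = model_scores[b][split]
                try:
                    pval = delong_paired_test(sa, sb, la)
                except ValueError:
                    # degenerate placements (e.g. a constant-score model
                    # against a perfect separator): no test is defined
                    pval = np.nan
                mat.loc[a, b] = mat.loc[b, a] = pval
        delong[split] = mat

    dca = {
        m: dca_net_benefit(model_scores[m][dca_split][0], model_scores[m][dca_split][1])
        for m in models
        if dca_split in model_scores[m]
    }
    return {"table": table, "delong": delong, "dca": dca}
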