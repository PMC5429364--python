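"""Per-residue classification metrics and curves.

Protean prediction is a heavily imbalanced binary problem (~2% positives),
so the metrics of interest are precision (PPV), recall (TPR), their harmonic
mean F1, and the Matthews correlation coefficient, plus recall-precision
curves (with trapezoidal AUC and the positive-fraction random baseline) and
"score plots" that overlay PPV, recall and F1 as functions of the score
cutoff. Metrics are micro-averaged: residues pooled across proteins and
folds before counting.

Zero-denominator convention: ppv/tpr/f1 are 0 when undefined, and mcc is 0
when any confusion-table marginal is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Published composition of the training corpora this predictor targets
#: (proteins, protean residues, non-protean residues, total residues).
#: The combined "PnM" row fixes the random-baseline precision: a uniformly
#: random classifier has expected precision equal to the positive fraction.
DATASET_TABLE: dict[str, dict[str, int]] = {
    "ProS": {"proteins": 557, "protean": 6245, "non_protean": 356053, "total": 362298},
    "MoRF": {"proteins": 840, "protean": 10549, "non_protean": 494264, "total": 504813},
    "PnM": {"proteins": 1397, "protean": 16794, "non_protean": 850317, "total": 867111},
    "validation": {"proteins": 9, "protean": 163, "non_protean": 2046, "total": 2209},
}
PNM_TABLE = DATASET_TABLE["PnM"]


def random_baseline_precision(table: dict[str, int] = PNM_TABLE) -> float:
    """Expected precision of a random classifier: the corpus positive fraction."""
    return table["protean"] / table["total"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int((calls & truth).sum()),
        tn=int((~calls & ~truth).sum()),
        fp=int((calls & ~truth).sum()),
        fn=int((~calls & truth).sum()),
    )


def ppv(c: ConfusionCounts) -> float:
    """Precision, TP/(TP+FP)."""
    den = c.tp + c.fp
    return c.tp / den if den else 0.0


def tpr(c: ConfusionCounts) -> float:
    """Recall, TP/(TP+FN)."""
    den = c.tp + c.fn
    return c.tp / den if den else 0.0


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall."""
    p, r = ppv(c), tpr(c)
    return 2 * p * r / (p + r) if p + r else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return ((c.tp * c.tn) - (c.fp * c.fn)) / math.sqrt(den)


def pr_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> dict:
    """Recall-precision curve over score cutoffs, with trapezoidal AUC.

    At each threshold t a residue is called positive when score >= t.
    Returns thresholds, precision, recall, the AUC over recall, and the
    positive-fraction random baseline.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores/truth length mismatch")
    if thresholds is None:
        thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order].astype(np.int64)
    tp_cum = np.cumsum(sorted_truth)
    n_pos = int(truth.sum())
    # number of calls at threshold t = count of scores >= t
    n_called = len(scores) - np.searchsorted(scores[order][::-1], thresholds, side="left")
    precision = np.zeros_like(thresholds)
    recall = np.zeros_like(thresholds)
    nz = n_called > 0
    precision[nz] = tp_cum[n_called[nz] - 1] / n_called[nz]
    if n_pos:
        recall[nz] = tp_cum[n_called[nz] - 1] / n_pos
    # Trapezoidal AUC over recall: use thresholds with at least one call,
    # collapse equal-recall points to their best precision (the attainable
    # upper envelope), and extend flat to recall 0.
    if nz.any():
        pts: dict[float, float] = {}
        for r_i, p_i in zip(recall[nz], precision[nz]):
            pts[r_i] = max(pts.get(r_i, 0.0), p_i)
        rs = np.array(sorted(pts))
        ps = np.array([pts[r_i] for r_i in rs])
        if rs[0] > 0.0:
            rs = np.concatenate([[0.0], rs])
            ps = np.concatenate([[ps[0]], ps])
        auc = float(np.trapezoid(ps, rs))
    else:
        auc = 0.0
    return {
        "thresholds": thresholds,
        "precision": precision,
        "recall": recall,
        "auc": auc,
        "baseline": n_pos / len(truth) if len(truth) else 0.0,
    }


def score_plot(
    scores: np.ndarray, truth: np.ndarray, bins: int = 100
) -> dict:
    """PPV, recall and F1 over a uniform cutoff grid; reports the F1 argmax."""
    grid = np.linspace(0.0, 1.0, bins + 1)
    curve = pr_curve(scores, truth, thresholds=grid)
    p, r = curve["precision"], curve["recall"]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    best = int(np.argmax(f))
    return {
        "cutoffs": grid,
        "ppv": p,
        "recall": r,
        "f1": f,
        "best_cutoff": float(grid[best]),
        "best_f1": float(f[best]),
    }


def summarize(calls: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Confusion counts and the four headline metrics in one dict."""
    c = confusion(calls, truth)
    return {
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
        "ppv": ppv(c), "tpr": tpr(c), "f1": f1(c), "mcc": mcc(c),
    }
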