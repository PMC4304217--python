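"""Ranking- and call-based performance metrics for DE benchmarking.

Given per-gene DE-evidence scores (for LFCseq, ``1 - prob_nonDE``) and
binary ground truth, computes ROC/AUC, the false-discovery-rate curve
over the top-k ranked genes, and precision / sensitivity / F-score for a
set of binary calls.  AUC uses the midrank convention for ties and
equals the probability that a random DE gene outranks a random non-DE
gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvalReport", "auc", "roc_points", "fdr_curve", "prf", "evaluate_result"]


@dataclass
class EvalReport:
    auc: float
    pre: float  # NaN when undefined (no calls made)
    sen: float
    fs: float   # NaN when pre or sen undefined, or both zero
    tp: int
    fp: int
    fn: int

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        for k in ("pre", "sen", "fs"):
            if np.isnan(d[k]):
                d[k] = None
        return json.dumps(d, **kwargs)


def _check_truth(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth).astype(int)
    if set(np.unique(truth)) - {0, 1}:
        raise ValueError("truth must be binary")
    return truth


def auc(scores, truth) -> float:
    """Area under the ROC curve of DE-evidence scores against truth."""
    truth = _check_truth(truth)
    if truth.min() == truth.max():
        raise ValueError("AUC needs both DE and non-DE genes in the truth")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def roc_points(scores, truth):
    """(FPR, TPR) points of the ROC curve."""
    truth = _check_truth(truth)
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def fdr_curve(scores, truth) -> np.ndarray:
    """FDR among the top-k genes, for every k.

    Genes are ranked by decreasing score; ties keep input order (stable).
    Returns an array of shape (G, 2) with columns (k, FDR(k) = FP/k).
    """
    truth = _check_truth(truth)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    fp = np.cumsum(1 - truth[order])
    k = np.arange(1, truth.size + 1)
    return np.column_stack([k, fp / k])


def prf(calls, truth) -> tuple[float, float, float]:
    """(precision, sensitivity, F-score); NaN where the quotient is undefined.

    Precision is NaN when no genes are called; F-score is NaN when either
    component is undefined or both are zero.
    """
    truth = _check_truth(truth)
    calls = np.asarray(calls).astype(int)
    tp = int(np.sum((calls == 1) & (truth == 1)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    pre = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    sen = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        fs = float("nan")
    else:
        fs = 2 * pre * sen / (pre + sen)
    return pre, sen, fs


def evaluate_result(result, truth) -> EvalReport:
    """Score a DE result table (columns prob_nonDE, de_call) against truth."""
    truth = _check_truth(truth)
    scores = 1.0 - result["prob_nonDE"].to_numpy(float)
    pre, sen, fs = prf(result["de_call"].to_numpy(int), truth)
    tp = int(np.sum((result["de_call"] == 1) & (truth == 1)))
    fp = int(np.sum((result["de_call"] == 1) & (truth == 0)))
    fn = int(np.sum((result["de_call"] == 0) & (truth == 1)))
    return EvalReport(auc=auc(scores, truth), pre=pre, sen=sen, fs=fs,
                      tp=tp, fp=fp, fn=fn)
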