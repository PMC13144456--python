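"""Brute-force reference implementations used only to check the metrics.

These deliberately use the most literal formulation of each definition
(pair counting, exhaustive threshold sweeps) and share no code with the
package implementation.
"""

import numpy as np


def confusion_by_pair_counting(y_true, y_pred, k=3):
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t][p] += 1
    return cm


def ovr_metrics_by_definition(cm):
    """Per-class TP/FP/FN/TN metrics straight from the printed formulas."""
    cm = np.asarray(cm)
    n = cm.sum()
    res = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = sum(cm[c, j] for j in range(cm.shape[0]) if j != c)
        fp = sum(cm[i, c] for i in range(cm.shape[0]) if i != c)
        tn = n - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        res.append((prec, rec, f1, spec))
    return res


def roc_auc_by_pair_counting(y_bin, scores):
    """P(score_pos > score_neg) with half credit for ties."""
    pos = scores[y_bin == 1]
    neg = scores[y_bin == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_by_threshold_sweep(y_bin, scores):
    """AP = sum over descending unique thresholds of (R_i - R_prev) * P_i."""
    thresholds = np.unique(scores)[::-1]
    n_pos = int(y_bin.sum())
    ap = 0.0
    r_prev = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((y_bin[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - r_prev) * precision
        r_prev = recall
    return ap


def log_loss_by_definition(y_true, probs, floor=1e-15):
    total = 0.0
    for i, y in enumerate(y_true):
        total -= np.log(max(probs[i][y], floor))
    return total / len(y_true)


def kappa_by_definition(cm):
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    po = sum(cm[i, i] for i in range(len(cm))) / n
    pe = sum(cm[i, :].sum() * cm[:, i].sum() for i in range(len(cm))) / n**2
    return (po - pe) / (1 - pe)


def mcc_by_definition(cm):
    """Multiclass MCC via the covariance formulation."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    t = cm.sum(axis=1)  # truth marginals
    p = cm.sum(axis=0)  # prediction marginals
    c = sum(cm[k, k] for k in range(len(cm)))
    num = c * n - float(t @ p)
    den = np.sqrt(n**2 - float(p @ p)) * np.sqrt(n**2 - float(t @ t))
    return num / den if den else 0.0
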