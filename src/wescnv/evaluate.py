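"""Window-level evaluation: confusion convention, derived metrics, locus
recurrence strata, the coordinate-only locus-prior baseline, and the
platform-shift robustness harness.

Every metric is computed at the level of individual exon windows, each with
one prediction and one truth label, via a 3x3 confusion matrix (rows =
truth, columns = prediction). Per-class metrics use a one-vs-rest
convention: a deletion predicted as a duplication contributes one false
negative for DEL *and* one false positive for DUP. Aggregates are macro
(unweighted) means over the three classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import ConvAttentionNet
from .simulate import PlatformShift, apply_platform_shift
from .train import EncodedDataset, TrainConfig, predict_proba
from .windows import DepthScaler, ExonWindow, labels_of

N_CLASSES = 3
STRATA = ("Never", "Rare", "Often", "Majority")


class DegenerateMetricError(ValueError):
    pass


def confusion_matrix3(y_true, y_pred) -> np.ndarray:
    """3x3 confusion counts; entry (i, j) = windows with truth i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= N_CLASSES):
            raise ValueError("labels must lie in {0, 1, 2}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def one_vs_rest_metrics(confusion: np.ndarray) -> dict:
    """Per-class precision/recall/F1/specificity + macro aggregates + accuracy.

    Zero-denominator metrics are reported as 0 and the affected class is
    listed under ``degenerate``.
    """
    cm = np.asarray(confusion, dtype=np.int64)
    total = cm.sum()
    if total == 0:
        raise DegenerateMetricError("empty confusion matrix")
    out = {"per_class": [], "degenerate": []}
    for c in range(N_CLASSES):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        prec, d1 = _safe_div(tp, tp + fp)
        rec, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * tp, 2 * tp + fp + fn)
        spec, d4 = _safe_div(tn, tn + fp)
        if d1 or d2 or d3 or d4:
            out["degenerate"].append(c)
        out["per_class"].append(
            {"precision": prec, "recall": rec, "f1": f1, "specificity": spec,
             "support": int(cm[c].sum())}
        )
    for key in ("precision", "recall", "f1", "specificity"):
        out[f"macro_{key}"] = float(np.mean([pc[key] for pc in out["per_class"]]))
    out["accuracy"] = float(np.trace(cm) / total)
    return out


def probability_metrics(y_true, probs) -> dict:
    """Per-class PR-AUC (average precision), macro ROC-AUC, and log loss."""
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (len(y_true), N_CLASSES):
        raise ValueError(f"probability array shape {probs.shape} invalid")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability triples must sum to 1")
    onehot = np.eye(N_CLASSES)[y_true]
    pr = [
        float(average_precision_score(onehot[:, c], probs[:, c]))
        for c in range(N_CLASSES)
    ]
    roc = float(roc_auc_score(y_true, probs, multi_class="ovr", average="macro"))
    log_loss = float(
        -np.log(np.maximum(probs[np.arange(len(y_true)), y_true], 1e-15)).mean()
    )
    return {
        "pr_auc_per_class": pr,
        "mean_pr_auc": float(np.mean(pr)),
        "roc_auc_macro": roc,
        "log_loss": log_loss,
    }


def agreement_metrics(confusion: np.ndarray) -> tuple[float, float]:
    """(Cohen's kappa, multiclass MCC) from the confusion matrix.

    Kappa compares observed to chance agreement from the marginals; MCC uses
    the multiclass covariance formulation.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    n = cm.sum()
    if n == 0:
        raise DegenerateMetricError("empty confusion matrix")
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    po = np.trace(cm) / n
    pe = float(row @ col) / n**2
    if pe >= 1.0:
        raise DegenerateMetricError("single-class input: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)
    cov_tp = np.trace(cm) * n - row @ col
    cov_t = n**2 - col @ col
    cov_p = n**2 - row @ row
    den = np.sqrt(cov_t * cov_p)
    mcc = float(cov_tp / den) if den > 0 else 0.0
    return float(kappa), mcc


@dataclass
class MetricReport:
    """Confusion matrix plus every derived per-class and aggregate metric."""

    confusion: np.ndarray
    per_class: list[dict]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    accuracy: float
    degenerate_classes: list[int] = field(default_factory=list)
    pr_auc_per_class: list[float] | None = None
    mean_pr_auc: float | None = None
    roc_auc_macro: float | None = None
    log_loss: float | None = None
    kappa: float | None = None
    mcc: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def per_class_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class, index=["NO-CALL", "DEL", "DUP"])
        if self.pr_auc_per_class is not None:
            df["pr_auc"] = self.pr_auc_per_class
        return df


def metric_report(y_true, y_pred, probs: np.ndarray | None = None) -> MetricReport:
    """Full evaluation of hard calls (and optionally probabilities)."""
    cm = confusion_matrix3(y_true, y_pred)
    ovr = one_vs_rest_metrics(cm)
    rep = MetricReport(
        confusion=cm,
        per_class=ovr["per_class"],
        macro_precision=ovr["macro_precision"],
        macro_recall=ovr["macro_recall"],
        macro_f1=ovr["macro_f1"],
        macro_specificity=ovr["macro_specificity"],
        accuracy=ovr["accuracy"],
        degenerate_classes=ovr["degenerate"],
    )
    try:
        rep.kappa, rep.mcc = agreement_metrics(cm)
    except DegenerateMetricError:
        pass
    if probs is not None:
        pm = probability_metrics(y_true, probs)
        rep.pr_auc_per_class = pm["pr_auc_per_class"]
        rep.mean_pr_auc = pm["mean_pr_auc"]
        rep.roc_auc_macro = pm["roc_auc_macro"]
        rep.log_loss = pm["log_loss"]
    return rep


# ---------------------------------------------------------------------------
# locus recurrence strata


def locus_frequency(training_windows: Sequence[ExonWindow]) -> dict[tuple, float]:
    """Per-locus CNV frequency: fraction of training samples labeled DEL or DUP.

    Loci are identified by (chrom, start, end); the denominator is the number
    of samples in which the locus appears.
    """
    seen: dict[tuple, set] = {}
    cnv: dict[tuple, set] = {}
    for w in training_windows:
        if w.label is None:
            raise ValueError("unlabeled training window")
        loc = w.locus
        seen.setdefault(loc, set()).add(w.sample_id)
        if w.label > 0:
            cnv.setdefault(loc, set()).add(w.sample_id)
    return {
        loc: len(cnv.get(loc, ())) / len(samples) for loc, samples in seen.items()
    }


def assign_stratum(frequency: float) -> str:
    """Never = {0}, Rare = (0, 0.05], Often = (0.05, 0.5], Majority = (0.5, 1]."""
    if frequency <= 0:
        return "Never"
    if frequency <= 0.05:
        return "Rare"
    if frequency <= 0.5:
        return "Often"
    return "Majority"


def stratified_recall(
    test_windows: Sequence[ExonWindow],
    predictions: np.ndarray,
    frequency_map: dict[tuple, float],
) -> pd.DataFrame:
    """Recall of true CNV windows stratified by training locus-CNV frequency.

    Only truth DEL/DUP windows are stratified (loci unseen in training count
    as Never). Two recall flavours per stratum: ``cnv_recall`` requires the
    exact true class; ``any_cnv_recall`` forgives DEL/DUP cross-calls.
    """
    y = labels_of(test_windows)
    pred = np.asarray(predictions, dtype=np.int64)
    rows = {s: {"n": 0, "exact": 0, "any": 0, "del_n": 0, "del_ok": 0,
                "dup_n": 0, "dup_ok": 0} for s in STRATA}
    for w, t, p in zip(test_windows, y, pred):
        if t == 0:
            continue
        s = assign_stratum(frequency_map.get(w.locus, 0.0))
        r = rows[s]
        r["n"] += 1
        r["exact"] += int(p == t)
        r["any"] += int(p > 0)
        key = "del" if t == 1 else "dup"
        r[f"{key}_n"] += 1
        r[f"{key}_ok"] += int(p == t)
    table = []
    for s in STRATA:
        r = rows[s]
        table.append({
            "stratum": s,
            "n_windows": r["n"],
            "cnv_recall": r["exact"] / r["n"] if r["n"] else np.nan,
            "any_cnv_recall": r["any"] / r["n"] if r["n"] else np.nan,
            "del_recall": r["del_ok"] / r["del_n"] if r["del_n"] else np.nan,
            "dup_recall": r["dup_ok"] / r["dup_n"] if r["dup_n"] else np.nan,
        })
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# locus-prior baseline


class LocusPriorBaseline:
    """Coordinate-only classifier quantifying locus-recurrence priors.

    Sees only the normalized start/end coordinates and the chromosome
    indicator — never a depth token — and is trained with the same head
    protocol (dense 256/128 ReLU + dropout, Adam, SMOTE, early stopping) as
    the depth model, so any performance gap isolates the depth signal.
    """

    N_FEATURES = 2 + 24

    def __init__(self, seed: int = 0):
        from .nnet import Adam, Dense, Dropout, softmax_xent  # noqa: F401
        rng = np.random.default_rng(seed)
        self.l1 = Dense(rng, self.N_FEATURES, 256, "relu")
        self.l2 = Dense(rng, 256, 128, "relu")
        self.out = Dense(rng, 128, 3, "linear")
        self.drop = Dropout(0.3)

    @staticmethod
    def features(ds: EncodedDataset) -> np.ndarray:
        """Coordinates + chromosome only; depth tokens are excluded by construction."""
        coords = ds.channels[:, 0, 1:3]  # broadcast start/end are position-constant
        return np.concatenate([coords, ds.chrom], axis=1).astype(np.float32)

    def _forward(self, x, rng=None, cache=None):
        from . import nnet

        def sub(name):
            if cache is None:
                return None
            cache[name] = {}
            return cache[name]

        h = self.l1.forward(x, sub("l1"))
        h = self.drop.forward(h, rng=rng, cache=sub("d1"))
        h = self.l2.forward(h, sub("l2"))
        h = self.drop.forward(h, rng=rng, cache=sub("d2"))
        logits = self.out.forward(h, sub("out"))
        if cache is not None:
            cache["logits"] = logits
        return nnet.softmax(logits, axis=1)

    def fit(self, train_ds: EncodedDataset, val_ds: EncodedDataset,
            config: TrainConfig = TrainConfig()) -> "LocusPriorBaseline":
        from .nnet import Adam, softmax_xent
        from .train import oversample_smote

        x, y = self.features(train_ds), train_ds.y
        if config.smote_enabled:
            x, y = oversample_smote(x, y, k_neighbors=config.smote_k_neighbors,
                                    seed=config.smote_seed)
        xv, yv = self.features(val_ds), val_ds.y
        params = [p for l in (self.l1, self.l2, self.out) for _, p in l.params()]
        opt = Adam(params, lr=config.learning_rate)
        shuffle_rng = np.random.default_rng(config.shuffle_seed)
        drop_rng = np.random.default_rng(config.dropout_seed)
        best_val, since, best = np.inf, 0, [p.copy() for p in params]
        for _ in range(config.max_epochs):
            order = shuffle_rng.permutation(len(y))
            for i in range(0, len(order), config.batch_size):
                b = order[i:i + config.batch_size]
                cache: dict = {}
                self._forward(x[b], rng=drop_rng, cache=cache)
                _, _, dlog = softmax_xent(cache["logits"], y[b])
                d = self.out.backward(dlog, cache["out"])
                d = self.drop.backward(d, cache["d2"])
                d = self.l2.backward(d, cache["l2"])
                d = self.drop.backward(d, cache["d1"])
                self.l1.backward(d, cache["l1"])
                opt.step([g for l in (self.l1, self.l2, self.out) for g in l.grads()])
            pv = self._forward(xv)
            val = float(-np.log(np.maximum(pv[np.arange(len(yv)), yv], 1e-15)).mean())
            if val < best_val:
                best_val, since = val, 0
                best = [p.copy() for p in params]
            else:
                since += 1
                if since >= config.early_stopping_patience:
                    break
        for p, bp in zip(params, best):
            p[...] = bp
        return self

    def predict_proba(self, ds: EncodedDataset) -> np.ndarray:
        return self._forward(self.features(ds))


def locus_prior_baseline(
    train_ds: EncodedDataset,
    val_ds: EncodedDataset,
    test_ds: EncodedDataset,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, MetricReport]:
    """Train the coordinate-only baseline and evaluate it on test windows."""
    clf = LocusPriorBaseline(seed).fit(train_ds, val_ds, config)
    probs = clf.predict_proba(test_ds)
    return probs, metric_report(test_ds.y, probs.argmax(axis=1), probs)


# ---------------------------------------------------------------------------
# platform robustness


def platform_robustness(
    model: ConvAttentionNet,
    windows: Sequence[ExonWindow],
    scaler: DepthScaler,
    shifts: Sequence[PlatformShift],
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the model under a set of platform shifts.

    Each shift perturbs the raw depths, which are then re-normalized with the
    *training* scaler (as a deployed model would) and scored; one row of
    overall / per-class F1 per shift setting.
    """
    rows = []
    for i, shift in enumerate(shifts):
        shifted = apply_platform_shift(windows, shift, seed=seed + i)
        ds = EncodedDataset.from_windows(shifted, scaler)
        probs = predict_proba(model, ds)
        rep = metric_report(ds.y, probs.argmax(axis=1), probs)
        rows.append({
            "name": shift.name or f"x{shift.factor:g}+n{shift.noise_scale:g}",
            "factor": shift.factor,
            "noise_scale": shift.noise_scale,
            "overall_f1": rep.macro_f1,
            "nc_f1": rep.per_class[0]["f1"],
            "del_f1": rep.per_class[1]["f1"],
            "dup_f1": rep.per_class[2]["f1"],
            "accuracy": rep.accuracy,
        })
    return pd.DataFrame(rows)
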