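"""Binary-classification evaluation: precision/recall/F1, AUC-ROC, average
precision, a repeated stratified cross-validation harness, and the
attention-head sweep."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EvalReport",
    "thresholded_metrics",
    "auc_roc",
    "average_precision",
    "evaluate_scores",
    "cross_validate",
    "head_sweep",
]


@dataclass
class EvalReport:
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    auc_roc: float = float("nan")
    average_precision: float = float("nan")
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "average_precision": self.average_precision,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "threshold": self.threshold,
        }


def _check(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    return scores, labels


def thresholded_metrics(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Precision, recall and F1 for the positive (sensitive) class.

    Zero-denominator cases (no predicted positives / no actual positives)
    yield metric 0 with a warning.
    """
    scores, labels = _check(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("degenerate confusion matrix: zero-denominator metrics set to 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return EvalReport(
        precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold
    )


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic (midranks)."""
    scores, labels = _check(scores, labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average method handles ties
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def average_precision(scores, labels) -> float:
    """AP = Σ_k (R_k − R_{k−1})·P_k over descending-score thresholds.

    Tied scores are grouped at a single threshold; R_0 = 0.
    """
    scores, labels = _check(scores, labels)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AP requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(np.sum(y[i:j] == 1))
        fp += int(np.sum(y[i:j] == 0))
        precision_k = tp / (tp + fp)
        recall_k = tp / n_pos
        ap += (recall_k - prev_recall) * precision_k
        prev_recall = recall_k
        i = j
    return ap


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report: thresholded metrics plus AUC and AP."""
    report = thresholded_metrics(scores, labels, threshold)
    report.auc_roc = auc_roc(scores, labels)
    report.average_precision = average_precision(scores, labels)
    return report


def cross_validate(
    fit_predict,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_repeats: int = 10,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Repeated stratified k-fold evaluation of a score-producing pipeline.

    ``fit_predict(X_train, y_train, X_test, seed)`` must return test scores in
    [0,1]. One row per metric with the mean and standard deviation across
    repeats (each repeat's value is its fold average).
    """
    X, y = np.asarray(X), np.asarray(y)
    if len(X) < n_folds:
        raise ValueError("fewer samples than folds")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("stratification infeasible: a class has fewer samples than folds")
    seeds = list(seeds) if seeds is not None else list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    metric_names = ["precision", "recall", "f1", "auc_roc", "average_precision"]
    per_repeat = {m: [] for m in metric_names}
    for seed in seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_vals = {m: [] for m in metric_names}
        for train_idx, test_idx in skf.split(X, y):
            scores = fit_predict(X[train_idx], y[train_idx], X[test_idx], seed)
            rep = evaluate_scores(scores, y[test_idx])
            for m in metric_names:
                fold_vals[m].append(getattr(rep, m))
        for m in metric_names:
            per_repeat[m].append(float(np.mean(fold_vals[m])))
    rows = [
        {"metric": m, "mean": float(np.mean(per_repeat[m])), "std": float(np.std(per_repeat[m]))}
        for m in metric_names
    ]
    return pd.DataFrame(rows)


def head_sweep(
    evaluate_fn,
    heads=(0, 2, 4, 8, 16, 32),
    token_dim: int = 64,
) -> pd.DataFrame:
    """Evaluate one pipeline per attention-head count on identical data/seeds.

    ``evaluate_fn(n_heads)`` returns an EvalReport. Head counts that do not
    divide ``token_dim`` are skipped with a warning and marked in the table.
    """
    rows = []
    for h in heads:
        if h > 0 and token_dim % h != 0:
            warnings.warn(f"skipping n_heads={h}: does not divide token_dim={token_dim}")
            rows.append({"n_heads": h, "status": "skipped: token_dim not divisible"})
            continue
        rep = evaluate_fn(h)
        rows.append({"n_heads": h, "status": "ok", **rep.as_dict()})
    return pd.DataFrame(rows)
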