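"""Diagnostic metrics, trade-off curves, histograms and fold aggregation.

Metrics follow diagnostic-test conventions: PPA (positive percent
agreement, i.e. sensitivity TP/(TP+FN)), NPA (negative percent agreement,
specificity TN/(TN+FP)) and PPV (positive predictive value, precision).
The decision rule is ``score >= t`` (ties predicted positive), with the
default operating threshold at 0.5. The trade-off curve sweeps every
distinct score as a threshold and records the false-negative and
true-negative rates relative to the *total* case count, which is the view
relevant to pre-screening: how many fusions are missed versus how many
confirmatory tests are saved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn import metrics as skm


@dataclass
class MetricsReport:
    roc_auc: float
    pr_auc: float
    accuracy: float
    ppa: float
    ppv: float
    npa: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    n: int
    auc_defined: bool = True
    sd_flag: bool = False

    def as_dict(self):
        return asdict(self)


@dataclass
class TradeoffCurve:
    thresholds: np.ndarray
    fn_rate: np.ndarray     # FN / n
    tn_rate: np.ndarray     # TN / n
    ppa: np.ndarray


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    return scores, labels


def confusion_at_threshold(scores, labels, t: float = 0.5):
    """Counts (tp, fp, tn, fn) under the rule: positive iff score >= t."""
    scores, labels = _check(scores, labels)
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def _safe_div(a, b):
    return a / b if b else 0.0


def summary_metrics(scores, labels, t: float = 0.5) -> MetricsReport:
    """Threshold metrics plus ROC AUC (Mann-Whitney) and step-wise PR AUC."""
    scores, labels = _check(scores, labels)
    tp, fp, tn, fn = confusion_at_threshold(scores, labels, t)
    n = len(labels)
    ppa = _safe_div(tp, tp + fn)
    ppv = _safe_div(tp, tp + fp)
    npa = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * ppv * ppa, ppv + ppa)
    both = 0 < labels.sum() < n
    if both:
        roc_auc = float(skm.roc_auc_score(labels, scores))
        pr_auc = float(skm.average_precision_score(labels, scores))
    else:
        roc_auc = pr_auc = float("nan")
    return MetricsReport(
        roc_auc=roc_auc, pr_auc=pr_auc,
        accuracy=_safe_div(tp + tn, n), ppa=ppa, ppv=ppv, npa=npa, f1=f1,
        tp=tp, fp=fp, tn=tn, fn=fn, threshold=t, n=n, auc_defined=bool(both))


def tradeoff_curve(scores, labels) -> TradeoffCurve:
    """Sweep all distinct scores (plus boundaries below the minimum and
    above the maximum) and record FN/n, TN/n and PPA at each threshold."""
    scores, labels = _check(scores, labels)
    if not (0 < labels.sum() < len(labels)):
        raise ValueError("both classes must be present")
    lo = min(0.0, scores.min())
    hi = np.nextafter(scores.max(), np.inf)
    ts = np.concatenate([[lo], np.unique(scores), [hi]])
    n = len(labels)
    fn_rate, tn_rate, ppa = [], [], []
    for t in ts:
        tp, fp, tn, fn = confusion_at_threshold(scores, labels, t)
        fn_rate.append(fn / n)
        tn_rate.append(tn / n)
        ppa.append(_safe_div(tp, tp + fn))
    return TradeoffCurve(thresholds=ts, fn_rate=np.array(fn_rate),
                         tn_rate=np.array(tn_rate), ppa=np.array(ppa))


def probability_histogram(scores, labels, bins: int = 20):
    """Per-class normalized histograms over bin edges covering [0, 1].

    Returns ``(edges, hist_neg, hist_pos)``; each histogram sums to 1 for a
    non-empty class and is empty (all zeros) otherwise.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    scores, labels = _check(scores, labels)
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = []
    for cls in (0, 1):
        vals = scores[labels == cls]
        if len(vals) == 0:
            out.append(np.zeros(bins))
            continue
        h, _ = np.histogram(np.clip(vals, 0, 1), bins=edges)
        out.append(h / h.sum())
    return edges, out[0], out[1]


def aggregate_folds(reports: list) -> dict:
    """Mean and sample (n-1) standard deviation of each metric across folds.

    With a single report the sd is reported as 0 and flagged.
    """
    if not reports:
        raise ValueError("need at least one report")
    keys = ("roc_auc", "pr_auc", "accuracy", "ppa", "ppv", "npa", "f1")
    single = len(reports) == 1
    out = {}
    for key in keys:
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        out[key] = {
            "mean": float(np.mean(vals)),
            "sd": 0.0 if single else float(np.std(vals, ddof=1)),
            "sd_flag": single,
        }
    return out


def stratified_report(scores, labels, strata, t: float = 0.5) -> dict:
    """summary_metrics on ALL plus each distinct stratum subset."""
    scores, labels = _check(scores, labels)
    strata = np.asarray(strata)
    if len(strata) != len(scores):
        raise ValueError("strata must align with scores")
    out = {"ALL": summary_metrics(scores, labels, t)}
    for name in sorted(set(strata.tolist())):
        sel = strata == name
        sub_labels = labels[sel]
        if len(sub_labels) == 0 or not (0 < sub_labels.sum() < len(sub_labels)):
            warnings.warn(f"stratum {name!r} empty or single-class; AUC undefined")
        if len(sub_labels) == 0:
            continue
        out[name] = summary_metrics(scores[sel], sub_labels, t)
    return out
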