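"""Classification metrics for binary and 8-way tumour classification.

Implements the full metric suite used in the study: accuracy, sensitivity
(recall), precision, specificity, F1, MCC, Cohen's kappa, two G-mean
variants, and ROC construction with trapezoidal AUC.  Two quantities are
deliberately reported in both a conventional and a literal variant:

* ``auc`` is the conventional trapezoidal ROC area (equivalently the
  Mann-Whitney pair statistic with ties counted 1/2); the literal printed
  formula sensitivity/specificity is also evaluated (``sens_spec_ratio``) as
  a secondary diagnostic because it cannot produce area-like values.
* ``g_mean`` follows the printed formula sqrt(precision*recall /
  (precision+recall)), whose maximum is sqrt(1/2); the conventional
  sqrt(sensitivity*specificity) is reported as ``g_mean_conventional``.

Undefined ratios (zero denominators) evaluate to 0 and are recorded in the
report's ``flags`` list rather than raising, so batch evaluation stays total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix", "AgreementStats", "MetricReport",
    "confusion", "rate_metrics", "mcc", "kappa", "gmean", "roc_auc",
    "multiclass_report", "binary_report",
]


@dataclass
class ConfusionMatrix:
    """K x K count table; rows = true class, columns = predicted class.

    For the binary case class 1 is "positive" (malignant), class 0
    "negative" (benign), giving the usual TP/TN/FP/FN view.
    """

    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.ndim != 2 or self.table.shape[0] != self.table.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.table < 0).any():
            raise ValueError("confusion-matrix cells must be >= 0")

    @classmethod
    def from_binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionMatrix":
        return cls(np.array([[tn, fp], [fn, tp]]))

    @property
    def K(self) -> int:
        return self.table.shape[0]

    @property
    def n(self) -> int:
        return int(self.table.sum())

    # binary views -----------------------------------------------------------
    def _require_binary(self) -> None:
        if self.K != 2:
            raise ValueError("binary view requires a 2x2 matrix")

    @property
    def tp(self) -> int:
        self._require_binary(); return int(self.table[1, 1])

    @property
    def tn(self) -> int:
        self._require_binary(); return int(self.table[0, 0])

    @property
    def fp(self) -> int:
        self._require_binary(); return int(self.table[0, 1])

    @property
    def fn(self) -> int:
        self._require_binary(); return int(self.table[1, 0])


@dataclass
class AgreementStats:
    """Observed/chance agreement and Cohen's kappa."""

    po: float
    pe: float
    kappa: float
    flags: list[str] = field(default_factory=list)


@dataclass
class MetricReport:
    values: dict[str, float]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    roc: list[tuple[float, float, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    schema_version: str = "1"

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": self.schema_version,
            "values": self.values,
            "per_class": self.per_class,
            "roc": [{"fpr": f, "tpr": t, "threshold": th} for f, t, th in self.roc],
            "flags": self.flags,
        }, indent=2)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def confusion(y_true, y_pred, K: int | None = None) -> ConfusionMatrix:
    """Tally cell (i, j) = number of records with true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if K is None:
        K = int(max(y_true.max(initial=0), y_pred.max(initial=0))) + 1
    table = np.zeros((K, K), dtype=np.int64)
    np.add.at(table, (y_true, y_pred), 1)
    return ConfusionMatrix(table)


def rate_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, sensitivity, precision, specificity and F1 for a binary table."""
    flags: list[str] = []
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", flags)
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1", flags)
    return MetricReport(values={"accuracy": acc, "sensitivity": sens,
                                "precision": prec, "specificity": spec,
                                "f1": f1}, flags=flags)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    Binary: the familiar (TP*TN - FP*FN) / sqrt of the four marginal
    products.  K > 2: the generalised multi-category form
    (c*s - sum t_k p_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)).
    Zero denominators give 0 by convention.
    """
    t = cm.table.astype(np.float64)
    if cm.K == 2:
        tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
        den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return 0.0 if den == 0 else (tp * tn - fp * fn) / den
    c = np.trace(t)
    s = t.sum()
    pk = t.sum(axis=0)   # predicted-class totals
    tk = t.sum(axis=1)   # true-class totals
    num = c * s - (tk * pk).sum()
    den = math.sqrt((s ** 2 - (pk ** 2).sum()) * (s ** 2 - (tk ** 2).sum()))
    return 0.0 if den == 0 else num / den


def kappa(cm: ConfusionMatrix) -> AgreementStats:
    """Cohen's kappa = (Po - Pe) / (1 - Pe) on any square count table."""
    flags: list[str] = []
    t = cm.table.astype(np.float64)
    n = t.sum()
    if n == 0:
        return AgreementStats(0.0, 0.0, 0.0, ["kappa: empty table"])
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n ** 2
    if pe == 1.0:
        return AgreementStats(po, pe, 0.0, ["kappa: Pe = 1, reported as 0"])
    return AgreementStats(po, pe, (po - pe) / (1.0 - pe), flags)


def gmean(precision: float, recall: float, sensitivity: float,
          specificity: float) -> tuple[float, float]:
    """(printed-formula G, conventional G).

    Printed formula: sqrt(precision*recall / (precision+recall)) - maximum
    sqrt(1/2).  Conventional: sqrt(sensitivity*specificity).
    """
    for v in (precision, recall, sensitivity, specificity):
        if not 0.0 <= v <= 1.0:
            raise ValueError("rate inputs must lie in [0, 1]")
    if precision + recall == 0:
        g_paper = 0.0
    else:
        g_paper = math.sqrt(precision * recall / (precision + recall))
    return g_paper, math.sqrt(sensitivity * specificity)


def roc_auc(y_true, scores) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points from a threshold sweep and trapezoidal AUC.

    Thresholds are the descending unique scores (plus a sentinel above the
    maximum); point k is (FPR, TPR) of the classifier "score >= threshold_k".
    The trapezoidal area equals the Mann-Whitney statistic P(score_pos >
    score_neg) + 0.5 P(tie).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last index of each tied score block
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist())), auc


def binary_report(y_true, y_pred, scores=None) -> MetricReport:
    """Full binary metric suite from labels, predictions and optional scores."""
    cm = confusion(y_true, y_pred, K=2)
    rep = rate_metrics(cm)
    v = rep.values
    v["mcc"] = mcc(cm)
    ag = kappa(cm)
    rep.flags.extend(ag.flags)
    v["kappa"] = ag.kappa
    g_paper, g_conv = gmean(v["precision"], v["sensitivity"],
                            v["sensitivity"], v["specificity"])
    v["g_mean"] = g_paper
    v["g_mean_conventional"] = g_conv
    # literal printed ratio at the default operating point
    v["sens_spec_ratio"] = (v["sensitivity"] / v["specificity"]
                            if v["specificity"] > 0 else 0.0)
    if scores is not None:
        rep.roc, v["auc"] = roc_auc(y_true, scores)
    return rep


def multiclass_report(cm: ConfusionMatrix) -> MetricReport:
    """Per-class one-vs-rest rates with macro and micro aggregates.

    Macro = unweighted mean over classes; micro = rates of the pooled
    one-vs-rest table (for single-label data micro precision = micro
    sensitivity = accuracy).  MCC uses the generalised K-way form; kappa is
    computed on the K x K table directly.
    """
    if cm.K < 2:
        raise ValueError("need K >= 2 classes")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    t = cm.table.astype(np.float64)
    n = t.sum()
    pooled = np.zeros(4)  # tp, fp, fn, tn over one-vs-rest expansions
    for k in range(cm.K):
        tp = t[k, k]
        fn = t[k].sum() - tp
        fp = t[:, k].sum() - tp
        tn = n - tp - fn - fp
        sub = rate_metrics(ConfusionMatrix.from_binary(int(tp), int(tn),
                                                       int(fp), int(fn)))
        flags.extend(f"class {k}: {f}" for f in sub.flags)
        per_class[str(k)] = sub.values
        pooled += (tp, fp, fn, tn)
    macro = {m: float(np.mean([per_class[str(k)][m] for k in range(cm.K)]))
             for m in ("accuracy", "sensitivity", "precision", "specificity", "f1")}
    tp, fp, fn, tn = pooled
    micro_flags: list[str] = []
    micro = {
        "accuracy": _safe_div(np.trace(t), n, "micro accuracy", micro_flags),
        "sensitivity": _safe_div(tp, tp + fn, "micro sensitivity", micro_flags),
        "precision": _safe_div(tp, tp + fp, "micro precision", micro_flags),
        "specificity": _safe_div(tn, tn + fp, "micro specificity", micro_flags),
    }
    micro["f1"] = _safe_div(2 * micro["precision"] * micro["sensitivity"],
                            micro["precision"] + micro["sensitivity"],
                            "micro f1", micro_flags)
    flags.extend(micro_flags)
    ag = kappa(cm)
    flags.extend(ag.flags)
    values = {f"macro_{k}": v for k, v in macro.items()}
    values.update({f"micro_{k}": v for k, v in micro.items()})
    values["mcc"] = mcc(cm)
    values["kappa"] = ag.kappa
    return MetricReport(values=values, per_class=per_class, flags=flags)
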