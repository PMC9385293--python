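"""Stratified splitting, classification metrics, and report generation.

Per-class precision/recall/F-measure are computed one-vs-rest from exact
confusion counts and reported in percent; ROC-AUC uses the threshold-sweep
curve (equivalent to the Mann-Whitney U statistic with ties counted 1/2).
Rounding to integer percent happens only at the presentation layer; all
internals keep full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "RocResult",
    "UndefinedMetricError",
    "train_test_split",
    "confusion_counts",
    "precision_recall_f",
    "f_measure",
    "roc_auc",
    "build_report",
]


class UndefinedMetricError(ValueError):
    """A metric denominator is zero (no predicted or no actual positives)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """One-vs-rest counts for a single positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass
class RocResult:
    """AUC plus the threshold-sweep curve points."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


@dataclass
class EvalReport:
    """Per-class precision/recall/F (%) with supports, averages, accuracy, AUC."""

    classes: list[str]
    precision: list[float]
    recall: list[float]
    f_measure: list[float]
    support: list[int]
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]
    accuracy: float
    auc: float = field(default=float("nan"))
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cls in enumerate(self.classes):
            rows.append((cls, self.precision[i], self.recall[i], self.f_measure[i],
                         self.support[i]))
        n = sum(self.support)
        rows.append(("macro avg", *self.macro_avg, n))
        rows.append(("weighted avg", *self.weighted_avg, n))
        return pd.DataFrame(
            rows, columns=["class", "precision_pct", "recall_pct", "f_measure_pct", "support"]
        )

    def to_csv(self, path: str | Path | None = None) -> str:
        df = self.to_frame()
        df.attrs = {}
        buf = StringIO()
        df.to_csv(buf, index=False)
        extra = (
            f"# accuracy_pct={self.accuracy!r} auc={self.auc!r}"
            f" flags={json.dumps(self.flags, separators=(',', ':'))}\n"
        )
        text = buf.getvalue() + extra
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": self.classes,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "f_measure_pct": self.f_measure,
            "support": self.support,
            "macro_avg": list(self.macro_avg),
            "weighted_avg": list(self.weighted_avg),
            "accuracy_pct": self.accuracy,
            "auc": self.auc,
            "flags": self.flags,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, text_or_path: str | Path) -> "EvalReport":
        text = text_or_path
        if isinstance(text_or_path, Path) or (
            isinstance(text_or_path, str) and "\n" not in text_or_path
        ):
            text = Path(text_or_path).read_text()
        lines = [ln for ln in str(text).splitlines() if ln.strip()]
        footer = [ln for ln in lines if ln.startswith("#")][0]
        body = "\n".join(ln for ln in lines if not ln.startswith("#"))
        df = pd.read_csv(StringIO(body), float_precision="round_trip")
        per_class = df[~df["class"].str.endswith("avg")]
        macro = df[df["class"] == "macro avg"].iloc[0]
        weighted = df[df["class"] == "weighted avg"].iloc[0]
        kv = dict(part.split("=") for part in footer[1:].split())
        return cls(
            classes=per_class["class"].tolist(),
            precision=per_class["precision_pct"].tolist(),
            recall=per_class["recall_pct"].tolist(),
            f_measure=per_class["f_measure_pct"].tolist(),
            support=[int(s) for s in per_class["support"]],
            macro_avg=(macro["precision_pct"], macro["recall_pct"], macro["f_measure_pct"]),
            weighted_avg=(
                weighted["precision_pct"], weighted["recall_pct"], weighted["f_measure_pct"]
            ),
            accuracy=float(kv["accuracy_pct"]),
            auc=float(kv["auc"]),
            flags=json.loads(kv.get("flags", "[]")),
        )


def train_test_split(
    items: list,
    labels: list | np.ndarray,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Stratified index split with ``round(n * train_fraction)`` training items.

    Per-class training counts are allocated by largest remainder, then clamped
    so that every class appears on both sides.  Returns (train_idx, test_idx).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    n = len(items)
    if labels.shape[0] != n:
        raise ValueError("items and labels disagree on n")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 members to appear on both sides")

    target = int(round(n * train_fraction))
    raw = counts * train_fraction
    alloc = np.floor(raw).astype(int)
    remainder = raw - alloc
    for i in np.argsort(-remainder, kind="stable"):
        if alloc.sum() >= target:
            break
        alloc[i] += 1
    alloc = np.clip(alloc, 1, counts - 1)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls, k in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        train_idx.extend(int(i) for i in idx[:k])
        test_idx.extend(int(i) for i in idx[k:])
    return sorted(train_idx), sorted(test_idx)


def confusion_counts(y_true, y_pred, positive) -> ConfusionMatrix:
    """One-vs-rest confusion counts for the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truths and predictions")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def precision_recall_f(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(precision %, recall %, F-measure %); raises if a denominator is zero."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("no predicted positives: precision undefined")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no actual positives: recall undefined")
    p = cm.tp / (cm.tp + cm.fp)
    r = cm.tp / (cm.tp + cm.fn)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return 100.0 * p, 100.0 * r, 100.0 * f


def f_measure(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, both given and returned in percent."""
    if precision_pct < 0 or recall_pct < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision_pct + recall_pct == 0:
        raise UndefinedMetricError("P + R = 0: F-measure undefined")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def roc_auc(scores, labels, positive=None) -> RocResult:
    """ROC-AUC with the full threshold-sweep curve.

    ``labels`` are binary; ``positive`` names the class the scores rank
    (default: the larger label).  AUC is the probability a positive outranks
    a negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("roc_auc needs exactly two classes present")
    if positive is None:
        positive = uniq[-1]
    y = (labels == positive).astype(int)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


def build_report(predictions, truths, scores=None, positive=None) -> EvalReport:
    """Full per-class + averaged report in the standard table layout.

    ``scores`` (optional) are scores for the ``positive`` class, used for AUC
    (default positive: the lexicographically larger label, matching
    :func:`roc_auc`).
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("length mismatch between predictions and truths")
    classes = sorted(np.unique(truths).tolist())
    precision, recall, fmeas, support = [], [], [], []
    flags: list[str] = []
    for cls in classes:
        cm = confusion_counts(truths, predictions, cls)
        try:
            p, r, f = precision_recall_f(cm)
        except UndefinedMetricError as exc:
            # degenerate predictions: flag the class, report NaN, keep going
            flags.append(f"{cls}: {exc}")
            p = r = f = float("nan")
        precision.append(p)
        recall.append(r)
        fmeas.append(f)
        support.append(cm.support)
    support_arr = np.asarray(support, dtype=float)
    wts = support_arr / support_arr.sum()
    macro = (float(np.mean(precision)), float(np.mean(recall)), float(np.mean(fmeas)))
    weighted = (
        float(np.dot(wts, precision)),
        float(np.dot(wts, recall)),
        float(np.dot(wts, fmeas)),
    )
    accuracy = 100.0 * float(np.mean(predictions == truths))
    auc = float("nan")
    if scores is not None:
        auc = roc_auc(scores, truths, positive=positive).auc
    return EvalReport(
        classes=[str(c) for c in classes],
        precision=precision,
        recall=recall,
        f_measure=fmeas,
        support=support,
        macro_avg=macro,
        weighted_avg=weighted,
        accuracy=accuracy,
        auc=auc,
        flags=flags,
    )
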