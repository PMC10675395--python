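"""Classification metrics, ROC/AUC curves and the regularizer comparison.

The four headline measures are computed from one-vs-rest confusion counts
per class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    F1          = 2 TP / (2 TP + FN + FP)

The three-state task is handled per class one-vs-rest, with an unweighted
macro average on top.  Degenerate 0/0 denominators evaluate to 0 (with a
logged warning).  ROC curves sweep the unique scores as thresholds and AUC
is the trapezoidal area, per class one-vs-rest plus the macro mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import STATES

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvaluationReport",
    "metrics",
    "confusion_counts",
    "roc_auc",
    "evaluate",
    "overfit_comparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    sensitivity: float
    f1: float


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; returning 0 by convention", name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity and F1 from confusion counts."""
    if counts.total == 0:
        raise InputError("cannot compute metrics on zero samples")
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=_safe_div(counts.tp, counts.tp + counts.fp, "precision"),
        sensitivity=_safe_div(counts.tp, counts.tp + counts.fn, "sensitivity"),
        f1=_safe_div(2 * counts.tp, 2 * counts.tp + counts.fn + counts.fp,
                     "F1"),
    )


def confusion_counts(y_true, y_pred, classes=STATES) -> dict:
    """Per-class one-vs-rest confusion counts plus a pooled 'micro' entry."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred differ in length")
    out = {}
    tp = tn = fp = fn = 0
    for c in classes:
        pos_t = y_true == c
        pos_p = y_pred == c
        cc = ConfusionCounts(
            tp=int((pos_t & pos_p).sum()),
            tn=int((~pos_t & ~pos_p).sum()),
            fp=int((~pos_t & pos_p).sum()),
            fn=int((pos_t & ~pos_p).sum()),
        )
        out[c] = cc
        tp += cc.tp
        tn += cc.tn
        fp += cc.fp
        fn += cc.fn
    out["micro"] = ConfusionCounts(tp, tn, fp, fn)
    return out


def roc_auc(scores: np.ndarray, labels, classes=STATES) -> dict:
    """One-vs-rest ROC points and trapezoidal AUC per class, plus macro.

    ``scores`` is (N, n_classes) of class probabilities aligned with
    ``classes``; every evaluated class needs at least one positive and one
    negative sample.
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve as _roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise InputError("scores must be (n_samples, n_classes)")
    roc = {}
    aucs = {}
    for j, c in enumerate(classes):
        pos = labels == c
        if pos.all() or not pos.any():
            raise InputError(
                f"AUC undefined for class {c!r}: need positives and negatives"
            )
        fpr, tpr, _ = _roc_curve(pos.astype(int), scores[:, j])
        roc[c] = (fpr, tpr)
        aucs[c] = float(_auc(fpr, tpr))
    aucs["macro"] = float(np.mean([aucs[c] for c in classes]))
    return {"roc": roc, "auc": aucs}


@dataclass
class EvaluationReport:
    """Metrics, ROC points and AUC for one evaluated sample set."""

    fold: int | None
    n_samples: int
    overall_accuracy: float
    per_class: dict          # class -> MetricSet
    macro: MetricSet
    auc: dict = field(default_factory=dict)    # class/macro -> float
    roc: dict = field(default_factory=dict)    # class -> (fpr, tpr) lists
    counts: dict = field(default_factory=dict)  # class -> ConfusionCounts
    indices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "n_samples": self.n_samples,
            "overall_accuracy": self.overall_accuracy,
            "per_class": {c: asdict(m) for c, m in self.per_class.items()},
            "macro": asdict(self.macro),
            "auc": self.auc,
            "roc": {c: [list(map(float, f)), list(map(float, t))]
                    for c, (f, t) in self.roc.items()},
            "counts": {c: asdict(cc) for c, cc in self.counts.items()},
            "indices": [int(i) for i in self.indices],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            fold=d["fold"],
            n_samples=d["n_samples"],
            overall_accuracy=d["overall_accuracy"],
            per_class={c: MetricSet(**m) for c, m in d["per_class"].items()},
            macro=MetricSet(**d["macro"]),
            auc=dict(d.get("auc", {})),
            roc={c: (list(f), list(t))
                 for c, (f, t) in d.get("roc", {}).items()},
            counts={c: ConfusionCounts(**cc)
                    for c, cc in d.get("counts", {}).items()},
            indices=list(d.get("indices", [])),
        )

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(s))


def evaluate(y_true, proba, classes=STATES, fold: int | None = None,
             indices=None) -> EvaluationReport:
    """Full report from true labels and predicted class probabilities."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(classes)[proba.argmax(axis=1)]
    counts = confusion_counts(y_true, y_pred, classes)
    per_class = {c: metrics(counts[c]) for c in classes}
    macro = MetricSet(*(float(np.mean([getattr(per_class[c], f)
                                       for c in classes]))
                        for f in ("accuracy", "precision", "sensitivity",
                                  "f1")))
    auc: dict = {}
    roc: dict = {}
    present = {c for c in classes
               if (y_true == c).any() and not (y_true == c).all()}
    if present == set(classes):
        ra = roc_auc(proba, y_true, classes)
        auc = ra["auc"]
        roc = {c: (list(map(float, f)), list(map(float, t)))
               for c, (f, t) in ra["roc"].items()}
    return EvaluationReport(
        fold=fold,
        n_samples=int(y_true.size),
        overall_accuracy=float((y_true == y_pred).mean()),
        per_class=per_class,
        macro=macro,
        auc=auc,
        roc=roc,
        counts=counts,
        indices=list(indices) if indices is not None else [],
    )


def plot_roc(report: EvaluationReport, path) -> None:
    """Write the report's one-vs-rest ROC curves as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, (fpr, tpr) in report.roc.items():
        ax.plot(fpr, tpr, label=f"{c} (AUC {report.auc.get(c, 0):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def overfit_comparison(images, labels, techniques=None,
                       config=None) -> pd.DataFrame:
    """Train one model per overfitting-mitigation technique, same data/seed.

    Techniques: 'kfold' (k-fold cross-validation, metrics averaged over
    folds) and the in-training regularizers 'L1', 'L2', 'dropout',
    'early_stopping' (single stratified train/test split).  Returns a table
    of accuracy/precision/sensitivity/F1 per technique.
    """
    from dataclasses import replace

    from .classifier import (TrainConfig, build_cnn, kfold_cv, predict_proba,
                             split_dataset, train)

    techniques = list(techniques or
                      ["kfold", "L1", "L2", "dropout", "early_stopping"])
    allowed = {"kfold", "L1", "L2", "dropout", "early_stopping"}
    unknown = set(techniques) - allowed
    if unknown:
        raise InputError(f"unknown technique(s): {sorted(unknown)}")
    config = config or TrainConfig()
    labels = np.asarray(labels)
    rows = {}
    for tech in techniques:
        if tech == "kfold":
            reports = kfold_cv(images, labels, k=config.folds,
                               config=replace(config, regularization="none"))
            rows[tech] = {
                "accuracy": float(np.mean([r.overall_accuracy
                                           for r in reports])),
                "precision": float(np.mean([r.macro.precision
                                            for r in reports])),
                "sensitivity": float(np.mean([r.macro.sensitivity
                                              for r in reports])),
                "f1": float(np.mean([r.macro.f1 for r in reports])),
            }
        else:
            cfg = replace(config, regularization=tech)
            tr, te = split_dataset(labels, config.train_fraction, config.seed)
            shape = np.asarray(images).shape[1:]
            model = build_cnn(input_shape=shape, seed=config.seed)
            model, _ = train(model, np.asarray(images)[tr], labels[tr], cfg)
            report = evaluate(labels[te],
                              predict_proba(model, np.asarray(images)[te]))
            rows[tech] = {
                "accuracy": report.overall_accuracy,
                "precision": report.macro.precision,
                "sensitivity": report.macro.sensitivity,
                "f1": report.macro.f1,
            }
    return pd.DataFrame(rows).T[["accuracy", "precision", "sensitivity",
                                 "f1"]]
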