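"""Classifier evaluation: confusion matrix, per-class report, PR/ROC curves.

Wraps scikit-learn's metric primitives behind the package's report
structures. Multi-class PR and ROC curves use one-vs-rest binarization
per class; metrics with an empty denominator are reported as 0 with a
warning (the zero-division convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn import metrics as skm

logger = logging.getLogger(__name__)

__all__ = ["ClassificationReport", "confusion_matrix", "classification_report",
           "curves", "write_report"]


@dataclass(frozen=True)
class ClassificationReport:
    per_class: dict  # class -> (precision, recall, f1, support)
    accuracy: float
    macro_avg: tuple  # (precision, recall, f1)
    weighted_avg: tuple

    def rounded(self, ndigits: int = 2) -> dict:
        """Table-style export rounded the way printed reports are."""
        return {
            "per_class": {c: tuple(round(v, ndigits) for v in vals[:3]) + (vals[3],)
                          for c, vals in self.per_class.items()},
            "accuracy": round(self.accuracy, ndigits),
            "macro_avg": tuple(round(v, ndigits) for v in self.macro_avg),
            "weighted_avg": tuple(round(v, ndigits) for v in self.weighted_avg),
        }


def _check_labels(y, classes):
    unknown = set(y) - set(classes)
    if unknown:
        raise ValueError(f"labels not in class list: {sorted(unknown)}")


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """C x C count matrix; entry (i, j) = true class i predicted as class j."""
    _check_labels(y_true, classes)
    _check_labels(y_pred, classes)
    return skm.confusion_matrix(y_true, y_pred, labels=list(classes))


def classification_report(y_true, y_pred, probabilities=None, classes=None) -> ClassificationReport:
    """Per-class precision/recall/F1/support with macro and weighted averages."""
    classes = list(classes) if classes is not None else sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, s = skm.precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0)
        mp, mr, mf, _ = skm.precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0)
        wp, wr, wf, _ = skm.precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0)
    if np.any((p == 0) | (r == 0)):
        logger.warning("zero-division convention applied: some metrics reported as 0")
    per_class = {c: (float(p[i]), float(r[i]), float(f[i]), int(s[i]))
                 for i, c in enumerate(classes)}
    accuracy = float(np.trace(cm) / cm.sum())
    return ClassificationReport(per_class=per_class, accuracy=accuracy,
                                macro_avg=(float(mp), float(mr), float(mf)),
                                weighted_avg=(float(wp), float(wr), float(wf)))


def curves(y_true, probabilities, classes) -> dict:
    """One-vs-rest PR and ROC curves with trapezoidal AUC per class.

    Classes absent from ``y_true`` are reported as ``missing`` (their
    one-vs-rest curves are undefined).
    """
    probabilities = np.asarray(probabilities)
    classes = list(classes)
    if probabilities.shape != (len(y_true), len(classes)):
        raise ValueError("probabilities must be n x C")
    out: dict = {}
    y = np.asarray(y_true)
    for i, c in enumerate(classes):
        pos = (y == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out[c] = {"missing": True}
            continue
        fpr, tpr, _ = skm.roc_curve(pos, probabilities[:, i])
        prec, rec, _ = skm.precision_recall_curve(pos, probabilities[:, i])
        out[c] = {
            "missing": False,
            "roc": (fpr, tpr),
            "roc_auc": float(skm.auc(fpr, tpr)),
            "pr": (rec[::-1], prec[::-1]),
            "average_precision": float(skm.average_precision_score(pos, probabilities[:, i])),
        }
    return out


def write_report(report: ClassificationReport, cm: np.ndarray, classes,
                 out_dir, curve_data: dict | None = None, plots: bool = True) -> None:
    """Write report.json, confusion.csv, per-class curve CSVs and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "per_class": {c: dict(zip(("precision", "recall", "f1", "support"), v))
                      for c, v in report.per_class.items()},
        "accuracy": report.accuracy,
        "macro_avg": dict(zip(("precision", "recall", "f1"), report.macro_avg)),
        "weighted_avg": dict(zip(("precision", "recall", "f1"), report.weighted_avg)),
        "rounded": report.rounded(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    header = "," + ",".join(str(c) for c in classes)
    rows = [f"{c}," + ",".join(str(int(v)) for v in cm[i]) for i, c in enumerate(classes)]
    (out / "confusion.csv").write_text(header + "\n" + "\n".join(rows) + "\n")
    if curve_data:
        cdir = out / "curves"
        cdir.mkdir(exist_ok=True)
        for c, d in curve_data.items():
            if d.get("missing"):
                continue
            fpr, tpr = d["roc"]
            np.savetxt(cdir / f"roc_{c}.csv", np.column_stack([fpr, tpr]),
                       delimiter=",", header="fpr,tpr", comments="")
            rec, prec = d["pr"]
            np.savetxt(cdir / f"pr_{c}.csv", np.column_stack([rec, prec]),
                       delimiter=",", header="recall,precision", comments="")
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
            for c, d in curve_data.items():
                if d.get("missing"):
                    continue
                axes[0].plot(*d["roc"], label=f"{c} (AUC={d['roc_auc']:.3f})")
                axes[1].plot(*d["pr"], label=f"{c} (AP={d['average_precision']:.3f})")
            axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
            axes[0].set(xlabel="FPR", ylabel="TPR", title="ROC (one-vs-rest)")
            axes[1].set(xlabel="Recall", ylabel="Precision", title="Precision-recall")
            for ax in axes:
                ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out / "curves.png", dpi=120)
            plt.close(fig)
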