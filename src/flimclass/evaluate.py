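"""Classification metrics, ROC/AUC, phenotype fractions and t-SNE.

Binary evaluation treats glycolysis as the positive class.  Multiclass
precision/recall/F1 are computed one-vs-rest per class and macro-averaged
(unweighted mean over classes); F1 is the harmonic mean
2 * P * R / (P + R).  The ROC is built from the predicted positive-class
probability with thresholds at the unique scores and the AUC obtained by
trapezoidal integration, which with midrank tie handling equals the
Mann-Whitney U statistic normalized by n_pos * n_neg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "binary_metrics",
    "multiclass_metrics",
    "confusion_matrix",
    "roc_curve",
    "auc_trapezoid",
    "phenotype_fractions",
    "tsne_embed",
]


@dataclass
class MetricsReport:
    """Confusion matrix (rows = truth, cols = predicted) and derived rates."""

    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    per_class: pd.DataFrame  # columns: precision, recall, f1; index: class
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float | None = None
    auc: float | None = None
    roc: pd.DataFrame | None = None
    positive_class: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.auc is not None:
            out["auc"] = self.auc
            out["positive_class"] = self.positive_class
        return out

    def summary(self) -> str:
        lines = [
            f"accuracy {self.accuracy:.4f}  macro P/R/F1 "
            f"{self.macro_precision:.4f}/{self.macro_recall:.4f}/"
            f"{self.macro_f1:.4f}"
        ]
        if self.auc is not None:
            lines.append(f"AUC ({self.positive_class} positive) {self.auc:.4f}")
        lines.append(str(self.per_class.round(4)))
        return "\n".join(lines)


def confusion_matrix(
    truth: np.ndarray, predicted: np.ndarray, classes: list[str]
) -> np.ndarray:
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        cm[index[t], index[p]] += 1
    return cm


def _per_class_rates(cm: np.ndarray, classes: list[str]) -> pd.DataFrame:
    rows = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        # recall is undefined for a class absent from the truth; an
        # unpredicted class that is present scores precision 0
        recall = tp / (tp + fn) if tp + fn > 0 else np.nan
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision = np.nan if np.isnan(recall) else 0.0
        if np.isnan(recall) or np.isnan(precision):
            f1 = np.nan
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows[cls] = {"precision": precision, "recall": recall, "f1": f1}
    return pd.DataFrame(rows).T


def roc_curve(
    truth_pos: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPR, TPR and thresholds from positive-class scores.

    Thresholds are the unique scores in decreasing order; ties collapse
    into a single ROC vertex (equivalent to midrank handling for the AUC).
    """
    truth_pos = np.asarray(truth_pos, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth_pos[order]
    distinct = np.where(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(t)[cut]
    fps = np.cumsum(~t)[cut]
    n_pos, n_neg = t.sum(), (~t).sum()
    tpr = np.r_[0.0, tps / max(n_pos, 1)]
    fpr = np.r_[0.0, fps / max(n_neg, 1)]
    thresholds = np.r_[np.inf, s[cut]]
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def binary_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    scores: np.ndarray | None = None,
    positive_class: str = "glycolysis",
) -> MetricsReport:
    """Two-class metrics with ROC/AUC; glycolysis is positive by default.

    ``scores`` are predicted probabilities of the positive class.  With a
    single-class truth vector the AUC is undefined and reported as None.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    classes = sorted(set(truth) | set(predicted))
    if positive_class not in classes:
        classes = sorted(set(classes) | {positive_class})
    # order as [positive, negatives...] for a conventional confusion layout
    classes = [positive_class] + [c for c in classes if c != positive_class]
    cm = confusion_matrix(truth, predicted, classes)
    per_class = _per_class_rates(cm, classes)
    accuracy = float(np.trace(cm) / cm.sum())

    auc = None
    roc = None
    if scores is not None:
        pos = truth == positive_class
        if 0 < pos.sum() < len(truth):
            fpr, tpr, thr = roc_curve(pos, np.asarray(scores, dtype=float))
            auc = auc_trapezoid(fpr, tpr)
            roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    valid = per_class.dropna()
    return MetricsReport(
        classes=classes,
        confusion=cm,
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(valid["precision"].mean()),
        macro_recall=float(valid["recall"].mean()),
        macro_f1=float(valid["f1"].mean()),
        auc=auc,
        roc=roc,
        positive_class=positive_class,
    )


def multiclass_metrics(
    truth: np.ndarray, predicted: np.ndarray, average: str = "macro"
) -> MetricsReport:
    """One-vs-rest per-class precision/recall/F1 with macro averaging.

    A class absent from the truth has undefined recall and is excluded
    from the macro averages.  ``average='micro'`` additionally reports
    micro-averaged precision in ``micro_precision``.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    classes = sorted(set(truth) | set(predicted))
    if len(set(truth)) < 2:
        raise ValueError("need at least 2 classes present in truth")
    cm = confusion_matrix(truth, predicted, classes)
    per_class = _per_class_rates(cm, classes)
    valid = per_class.dropna()
    if len(valid) < len(per_class):
        import warnings

        missing = sorted(set(per_class.index) - set(valid.index))
        warnings.warn(
            f"classes with undefined rates excluded from macro average: {missing}",
            stacklevel=2,
        )
    micro = float(np.trace(cm) / cm.sum()) if average == "micro" else None
    return MetricsReport(
        classes=classes,
        confusion=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
        per_class=per_class,
        macro_precision=float(valid["precision"].mean()),
        macro_recall=float(valid["recall"].mean()),
        macro_f1=float(valid["f1"].mean()),
        micro_precision=micro,
    )


def phenotype_fractions(predicted: np.ndarray) -> pd.DataFrame:
    """Counts and percentages per predicted phenotype (sums to 100%)."""
    predicted = np.asarray(predicted)
    if len(predicted) == 0:
        raise ValueError("need at least one prediction")
    counts = pd.Series(predicted).value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / counts.sum()}
    )


def tsne_embed(
    features: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of an (n, d) feature matrix."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 5:
        raise ValueError(f"t-SNE needs at least 5 samples, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(features)
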