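"""Per-class precision/recall/F1, micro-F1, and confusion reconstruction.

For class c with true positives TP, false positives FP and false negatives FN:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

and over all classes the micro-F1 = 2 sum TP / (2 sum TP + sum FP + sum FN),
which for single-label classification equals plain accuracy.

:func:`reconstruct_confusion` inverts rounded printed precision/recall
percentages back into the unique integer confusion matrix they came from
(given the known per-class test sizes) — useful for checking reported
two-class results when only the rounded percentages survive in print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

#: reported per-window test-set performance of the original cohort analysis
#: (precision/recall percent for the upward-linear and S-shape classes, test
#: composition 3 + 4) together with each window's winning classifier family.
REFERENCE_WINDOW_PERFORMANCE = {
    5: {"precision_pct": (50, 67), "recall_pct": (67, 50),
        "class_sizes": (3, 4), "final_model": "cosine k-nearest neighbor"},
    6: {"precision_pct": (75, 100), "recall_pct": (100, 75),
        "class_sizes": (3, 4), "final_model": "linear support vector machine"},
    7: {"precision_pct": (100, 100), "recall_pct": (100, 100),
        "class_sizes": (3, 4), "final_model": "cosine k-nearest neighbor"},
    8: {"precision_pct": (60, 100), "recall_pct": (100, 50),
        "class_sizes": (3, 4), "final_model": "cosine k-nearest neighbor"},
}

REFERENCE_CLASS_NAMES = ("upward_linear", "s_shape")


def round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0 ** decimals
    return np.floor(x * f + 0.5) / f


@dataclass
class ConfusionMatrix:
    labels: list
    table: np.ndarray  # table[i, j] = count of true label i predicted as j

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        k = len(self.labels)
        if self.table.shape != (k, k) or (self.table < 0).any():
            raise ValueError("confusion table must be k x k with nonnegative counts")

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.table)

    def fp(self) -> np.ndarray:
        return self.table.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.table.sum(axis=1) - self.tp()


def confusion(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """k x k contingency table; predictions outside the label set are an error."""
    yt = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if yt.size != yp.size:
        raise ValueError("length mismatch")
    if labels is None:
        labels = sorted(np.unique(yt).tolist())
    unseen = set(np.unique(yp).tolist()) - set(labels)
    if unseen:
        raise ValueError(f"predictions contain unseen label(s) {sorted(unseen)}")
    return ConfusionMatrix(list(labels), _sk_confusion(yt, yp, labels=labels))


def class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall/F1 dict keyed by label.

    Degenerate conventions: a class with TP = 0 but some FP or FN scores 0;
    a class absent from both truth and predictions is undefined and reported
    as NaN with a warning.
    """
    out = {}
    for i, lab in enumerate(cm.labels):
        tp = int(cm.tp()[i])
        fp = int(cm.fp()[i])
        fn = int(cm.fn()[i])
        if tp == 0 and fp == 0 and fn == 0:
            warnings.warn(f"class {lab!r} absent from truth and predictions; metrics NaN")
            out[lab] = {"precision": float("nan"), "recall": float("nan"),
                        "f1": float("nan")}
            continue
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn)
        out[lab] = {"precision": p, "recall": r, "f1": f1}
    return out


def micro_f1(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp = int(cm.tp().sum())
    fp = int(cm.fp().sum())
    fn = int(cm.fn().sum())
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    per_class: dict
    micro_f1: float

    def to_dict(self) -> dict:
        return {
            "labels": self.confusion.labels,
            "confusion": self.confusion.table.tolist(),
            "per_class": self.per_class,
            "micro_f1": self.micro_f1,
        }


def evaluate(true_labels, predicted_labels, labels=None) -> EvaluationReport:
    cm = confusion(true_labels, predicted_labels, labels)
    return EvaluationReport(cm, class_metrics(cm), micro_f1(cm))


def reconstruct_confusion(precision_pct, recall_pct, class_sizes,
                          labels=None) -> list[ConfusionMatrix]:
    """All two-class confusion matrices consistent with rounded percentages.

    Enumerates integer TP per class (FN follows from the class size and, in
    the two-class case, each class's FP equals the other's FN) and keeps the
    matrices whose half-up-rounded precision and recall percentages match the
    printed integers.  An empty result signals a transcription mistake.
    """
    precision_pct = tuple(precision_pct)
    recall_pct = tuple(recall_pct)
    sizes = tuple(int(s) for s in class_sizes)
    if len(sizes) != 2:
        raise ValueError("reconstruction implemented for the two-class case")
    if labels is None:
        labels = [f"class{i + 1}" for i in range(2)]

    sols = []
    for tp0 in range(sizes[0] + 1):
        for tp1 in range(sizes[1] + 1):
            table = np.array([[tp0, sizes[0] - tp0],
                              [sizes[1] - tp1, tp1]])
            cm = ConfusionMatrix(list(labels), table)
            ok = True
            for i, (p_print, r_print) in enumerate(zip(precision_pct, recall_pct)):
                tp = cm.tp()[i]
                fp = cm.fp()[i]
                fn = cm.fn()[i]
                if tp + fp == 0:
                    ok = False
                    break
                p = round_half_up(100 * tp / (tp + fp))
                r = round_half_up(100 * tp / (tp + fn))
                if p != p_print or r != r_print:
                    ok = False
                    break
            if ok:
                sols.append(cm)
    if not sols:
        raise ValueError("no integer confusion matrix matches the printed values")
    return sols
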