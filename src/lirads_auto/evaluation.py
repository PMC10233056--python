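"""Evaluation suite: DICE, threshold sweeps, multi-level detection metrics,
and the LI-RADS confusion matrix.

Two DICE aggregations are distinguished.  The *average local* DICE computes
``2TP/(2TP+FP+FN)`` per patient and averages the values; the *global* DICE
pools the counts over patients first and computes one ratio.  With many
small, hard lesions the local average is dragged down by per-patient zeros
while the global value stays high — both are reported.

Detection is assessed at three granularities: pixel (pooled counts per
threshold), lesion (a ground-truth component counts as detected when a
predicted component overlaps it under the match rule; unmatched predictions
are false positives; true negatives are undefined at this level), and patient
(a patient is detected when any of their lesions is; a lesion-free patient
with any predicted component is a patient-level false positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PixelCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "PixelCounts") -> "PixelCounts":
        return PixelCounts(self.TP + other.TP, self.FP + other.FP,
                           self.FN + other.FN, self.TN + other.TN)


def counts_from_masks(pred: np.ndarray, truth: np.ndarray) -> PixelCounts:
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth grids differ")
    return PixelCounts(
        TP=int((p & t).sum()), FP=int((p & ~t).sum()),
        FN=int((~p & t).sum()), TN=int((~p & ~t).sum()),
    )


def dice_from_counts(counts: PixelCounts) -> float:
    """``2TP/(2TP+FP+FN)``; defined as 0 when the denominator is 0."""
    den = 2 * counts.TP + counts.FP + counts.FN
    return 2 * counts.TP / den if den > 0 else 0.0


def local_dice_mean(per_patient_counts: list[PixelCounts],
                    empty_vs_empty: float = 0.0) -> float:
    """Unweighted mean of per-patient DICE values.

    ``empty_vs_empty`` sets the DICE of a patient where both truth and
    prediction are empty (0 by default; 1 treats "no lesion, none predicted"
    as perfect).
    """
    if not per_patient_counts:
        raise ValueError("need at least one patient")
    vals = [
        empty_vs_empty if (2 * c.TP + c.FP + c.FN) == 0 else dice_from_counts(c)
        for c in per_patient_counts
    ]
    return float(np.mean(vals))


def global_dice(per_patient_counts: list[PixelCounts]) -> float:
    """DICE of the pooled counts: ``2*sum TP / (2*sum TP + sum FP + sum FN)``."""
    if not per_patient_counts:
        raise ValueError("need at least one patient")
    total = PixelCounts()
    for c in per_patient_counts:
        total = total + c
    return dice_from_counts(total)


def pixel_metric_sweep(prob_maps, truth_masks, thresholds):
    """Pooled pixel-level precision/recall/specificity/FPR per threshold.

    ``prob_maps`` and ``truth_masks`` are parallel sequences of aligned
    arrays.  Recall, sensitivity, and the true-positive rate are the same
    quantity and reported once.  Precision with zero predicted positives is
    reported as 1 with ``degenerate_precision`` flagged.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list is empty")
    rows = []
    for thr in thresholds:
        total = PixelCounts()
        for pm, tm in zip(prob_maps, truth_masks):
            total = total + counts_from_masks(np.asarray(pm) >= thr, tm)
        n_pred = total.TP + total.FP
        n_pos = total.TP + total.FN
        n_neg = total.TN + total.FP
        rows.append(
            {
                "threshold": float(thr),
                "precision": total.TP / n_pred if n_pred else 1.0,
                "degenerate_precision": n_pred == 0,
                "recall": total.TP / n_pos if n_pos else 0.0,
                "specificity": total.TN / n_neg if n_neg else 1.0,
                "fpr": total.FP / n_neg if n_neg else 0.0,
                "dice": dice_from_counts(total),
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)


@dataclass
class DetectionResult:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    degenerate_precision: bool = False


def lesion_level_metrics(
    pred_labelled: np.ndarray,
    true_labelled: np.ndarray,
    iou_threshold: float | None = None,
) -> DetectionResult:
    """Lesion-level detection counts from two labelled component maps.

    A true lesion is detected (TP) when a predicted component overlaps it —
    by at least one shared voxel by default, or with IoU >= ``iou_threshold``
    when given.  Predicted components matching no true lesion are FP; missed
    true lesions are FN.  True negatives are undefined at lesion level.
    Splitting one prediction into several components overlapping the same
    true lesion still yields a single TP.
    """
    pred_labels = [int(l) for l in np.unique(pred_labelled) if l != 0]
    true_labels = [int(l) for l in np.unique(true_labelled) if l != 0]
    detected = set()
    matched_preds = set()
    for tl in true_labels:
        t = true_labelled == tl
        for pl in pred_labels:
            p = pred_labelled == pl
            inter = int((t & p).sum())
            if inter == 0:
                continue
            if iou_threshold is not None:
                union = int((t | p).sum())
                if inter / union < iou_threshold:
                    continue
            detected.add(tl)
            matched_preds.add(pl)
    tp = len(detected)
    fn = len(true_labels) - tp
    fp = len(pred_labels) - len(matched_preds)
    n_pred = len(pred_labels)
    precision = (n_pred - fp) / n_pred if n_pred else 1.0
    recall = tp / len(true_labels) if true_labels else 0.0
    return DetectionResult(TP=tp, FP=fp, FN=fn, precision=precision,
                           recall=recall, degenerate_precision=n_pred == 0)


def patient_level_metrics(per_patient: list[tuple[DetectionResult, bool]]) -> DetectionResult:
    """Patient-level detection from per-patient lesion results.

    ``per_patient`` pairs each patient's lesion-level result with a flag
    saying whether the patient truly has lesions.  A lesion-bearing patient
    is a TP when at least one lesion was detected, otherwise an FN; a
    lesion-free patient with any predicted component is an FP.
    """
    tp = fp = fn = 0
    n_pred_pos = 0
    for res, has_lesions in per_patient:
        predicted_any = (res.TP + res.FP) > 0
        if has_lesions:
            if res.TP > 0:
                tp += 1
            else:
                fn += 1
            if predicted_any:
                n_pred_pos += 1
        elif predicted_any:
            fp += 1
            n_pred_pos += 1
    n_true_pos = tp + fn
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / n_true_pos if n_true_pos else 0.0
    return DetectionResult(TP=tp, FP=fp, FN=fn, precision=precision,
                           recall=recall, degenerate_precision=(tp + fp) == 0)


LR_CLASSES = ("LR-3", "LR-4", "LR-5")


def confusion_and_accuracy(predicted, true):
    """3x3 confusion matrix over LR-3/4/5 (rows = true, cols = predicted)
    plus overall accuracy and the over/under-categorization triangle sums."""
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise ValueError("prediction and truth lists differ in length")
    index = {c: i for i, c in enumerate(LR_CLASSES)}
    mat = np.zeros((3, 3), dtype=int)
    for p, t in zip(predicted, true):
        if p not in index or t not in index:
            raise ValueError(f"label outside {LR_CLASSES}: {p!r} / {t!r}")
        mat[index[t], index[p]] += 1
    total = mat.sum()
    accuracy = float(np.trace(mat) / total) if total else float("nan")
    over = int(np.triu(mat, 1).sum())   # predicted higher than truth
    under = int(np.tril(mat, -1).sum())
    return mat, accuracy, {"overcategorized": over, "undercategorized": under}


@dataclass
class EvalReport:
    """Bundle of everything the evaluation stage produces."""

    threshold_table: "pandas.DataFrame"
    per_patient_dice: dict
    lesion_detection: DetectionResult
    patient_detection: DetectionResult
    confusion: np.ndarray | None = None
    accuracy: float | None = None

    def to_dict(self) -> dict:
        out = {
            "thresholds": self.threshold_table.to_dict(orient="records"),
            "per_patient_dice": {k: float(v) for k, v in self.per_patient_dice.items()},
            "lesion_detection": vars(self.lesion_detection),
            "patient_detection": vars(self.patient_detection),
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
            out["accuracy"] = self.accuracy
        return out
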