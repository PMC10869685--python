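"""Classification and detection evaluation, and grouped cross-validation.

The positive class is *abnormal* throughout: sensitivity (recall on abnormal
breasts) is the screening-critical quantity. Cross-validation groups by study
ID so that no patient contributes images to both sides of any split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detect import BoundingBox, iou
from .dualview_net import TrainConfig, train
from .imaging import BreastExam

logger = logging.getLogger("dvscreen.evaluate")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with abnormal as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix for binary labels/predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"labels and predictions differ in length: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(tp=int(((y == 1) & (p == 1)).sum()),
                           fp=int(((y == 0) & (p == 1)).sum()),
                           fn=int(((y == 1) & (p == 0)).sum()),
                           tn=int(((y == 0) & (p == 0)).sum()))


def metrics(cm: ConfusionMatrix) -> dict:
    """Precision, recall, F1 and accuracy from a confusion matrix.

    A ratio with a zero denominator is reported as 0.0 and its name is listed
    under the ``undefined`` key, which keeps averaging over folds well-defined
    while preserving the information that the value is a convention.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision + recall == 0:
        if "precision" not in undefined and "recall" not in undefined:
            undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy,
            "undefined": undefined}


def auc_roc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (trapezoidal; ties averaged, i.e. the
    normalized Mann–Whitney U statistic). Requires both classes present."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if y.min() == y.max():
        raise ValueError("auc_roc needs both classes present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, s))


def _as_image_lists(boxes) -> list[list[BoundingBox]]:
    if boxes and isinstance(boxes[0], BoundingBox):
        return [list(boxes)]
    return [list(b) for b in boxes] if boxes else [[]]


def average_precision(pred_boxes, gt_boxes, iou_threshold: float = 0.5,
                      class_name: str | None = None) -> float:
    """Detection AP for one class via greedy matching and all-point interpolation.

    ``pred_boxes`` / ``gt_boxes`` are parallel per-image box lists (a single
    flat list is treated as one image). Predictions are visited in descending
    objectness; each may claim the best-IoU unmatched ground-truth box of the
    same image at IoU >= ``iou_threshold``. AP integrates the precision
    envelope over recall (all-point interpolation).
    """
    preds_per_img = _as_image_lists(pred_boxes)
    gts_per_img = _as_image_lists(gt_boxes)
    if len(preds_per_img) != len(gts_per_img):
        raise ValueError("pred and gt image lists differ in length")
    if class_name is not None:
        preds_per_img = [[b for b in img if b.class_name == class_name] for img in preds_per_img]
        gts_per_img = [[b for b in img if b.class_name == class_name] for img in gts_per_img]
    n_gt = sum(len(g) for g in gts_per_img)
    flat = [(i, b) for i, img in enumerate(preds_per_img) for b in img]
    if n_gt == 0:
        return 0.0
    if not flat:
        return 0.0
    flat.sort(key=lambda ib: (-ib[1].objectness, ib[0], ib[1].x_min, ib[1].y_min))
    matched: list[set[int]] = [set() for _ in gts_per_img]
    tp = np.zeros(len(flat))
    for k, (i, pb) in enumerate(flat):
        best_j, best_iou = -1, 0.0
        for j, gb in enumerate(gts_per_img[i]):
            if j in matched[i]:
                continue
            v = iou(pb, gb)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[i].add(best_j)
            tp[k] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(flat) + 1)
    recall = cum_tp / n_gt
    # All-point interpolation: integrate the running-max-from-the-right envelope.
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for k in range(len(mpre) - 2, -1, -1):
        mpre[k] = max(mpre[k], mpre[k + 1])
    steps = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * mpre[steps + 1]))


def mean_average_precision(pred_boxes, gt_boxes, iou_threshold: float = 0.5) -> dict:
    """mAP over the classes present in the ground truth, plus per-class AP."""
    gts_per_img = _as_image_lists(gt_boxes)
    classes = sorted({b.class_name for img in gts_per_img for b in img})
    if not classes:
        return {"mAP": 0.0, "per_class": {}}
    per_class = {c: average_precision(pred_boxes, gt_boxes, iou_threshold, class_name=c)
                 for c in classes}
    return {"mAP": float(np.mean(list(per_class.values()))), "per_class": per_class}


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per record; all records of one study share a fold."""

    fold_index: tuple[int, ...]
    k: int


def group_kfold(study_ids: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Deal studies into k folds: shuffle unique studies with ``seed``, then
    round-robin. Fold sizes differ by at most one study and no study ever
    spans two folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = sorted(set(study_ids))
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct studies, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    fold_of_study = {sid: i % k for i, sid in enumerate(order)}
    return FoldAssignment(fold_index=tuple(fold_of_study[s] for s in study_ids), k=k)


def train_test_split_by_study(exams: Sequence[BreastExam], test_fraction: float = 0.2,
                              seed: int = 0) -> tuple[list[BreastExam], list[BreastExam]]:
    """Reserve a held-out test set by study (default 20%), seeded."""
    unique = sorted({e.study_id for e in exams})
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    n_test = max(1, round(test_fraction * len(unique)))
    test_sids = set(order[:n_test])
    train_set = [e for e in exams if e.study_id not in test_sids]
    test_set = [e for e in exams if e.study_id in test_sids]
    return train_set, test_set


def _eval_split(model, exams: Sequence[BreastExam], prob_threshold: float = 0.5) -> dict:
    y = np.array([e.label for e in exams], dtype=int)
    scores = model.predict_proba(exams)
    preds = (scores > prob_threshold).astype(int)
    cm = confusion(y, preds)
    out = {"confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
           **metrics(cm), "roc": {"labels": y.tolist(), "scores": scores.tolist()}}
    if 0 < y.sum() < len(y):
        out["auc"] = auc_roc(y, scores)
    return out


def cross_validate(exams: Sequence[BreastExam], cfg: TrainConfig | None = None,
                   k: int = 5, test_fraction: float = 0.2, seed: int = 0) -> dict:
    """Grouped k-fold cross-validation with a study-level held-out test set.

    The test split is reserved first with a fixed seed; each fold then trains
    the full dual-view pipeline on the remaining studies minus the fold's
    validation studies, and evaluates on both the fold's validation set and
    the untouched test set. Any study appearing on both sides of a fold is a
    hard error.
    """
    cfg = cfg or TrainConfig()
    dev, test = train_test_split_by_study(exams, test_fraction, seed)
    assign = group_kfold([e.study_id for e in dev], k=k, seed=seed)
    folds: list[dict] = []
    for fold in range(k):
        val = [e for e, f in zip(dev, assign.fold_index) if f == fold]
        tr = [e for e, f in zip(dev, assign.fold_index) if f != fold]
        overlap = {e.study_id for e in tr} & {e.study_id for e in val}
        if overlap:
            raise RuntimeError(f"fold {fold}: study leakage {sorted(overlap)[:5]}")
        model, history = train(tr, val, cfg)
        folds.append({"fold": fold, "n_train": len(tr), "n_val": len(val),
                      "val": _eval_split(model, val),
                      "test": _eval_split(model, test) if test else None,
                      "epochs_run": len(history)})
    mean: dict[str, float] = {}
    for split in ("val", "test"):
        rows = [f[split] for f in folds if f[split] is not None]
        if rows:
            for key in ("precision", "recall", "f1", "accuracy"):
                mean[f"{split}_{key}"] = float(np.mean([r[key] for r in rows]))
            aucs = [r["auc"] for r in rows if "auc" in r]
            if aucs:
                mean[f"{split}_auc"] = float(np.mean(aucs))
    return {"k": k, "folds": folds, "mean": mean,
            "n_test_breasts": len(test), "n_dev_breasts": len(dev)}
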