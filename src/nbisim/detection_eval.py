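"""Detection evaluation: IoU/GIoU, YOLO reference losses, Table-style metrics.

The package consumes an external detector's outputs (class, confidence,
box per image) and evaluates them against ground truth:

* geometric primitives: IoU and generalized IoU (GIoU = IoU − (A_c − U)/A_c
  with A_c the smallest enclosing box area, U the union);
* the three YOLO loss terms — GIoU box-regression loss, confidence
  binary cross-entropy with a λ_noobj-weighted no-object term, and
  per-class classification BCE — as reference computations over an
  S²-cell, B-slot grid;
* PASCAL-style greedy matching at IoU ≥ 0.5 producing per-class confusion
  counts, the five summary metrics (precision, recall, specificity,
  accuracy, F1) and all-point-interpolated AP50 / mAP50.

Negatives for a detector are ill-defined at box level; specificity and
accuracy use image-level true negatives (images with neither ground truth
nor detections of the class), stated prominently in written reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import Annotation, Box, LesionClass

logger = logging.getLogger(__name__)

DEFAULT_IOU_THRESHOLD = 0.5
#: Confidence weight for grid slots that contain no object (value not
#: standardized; configurable).
DEFAULT_LAMBDA_NOOBJ = 0.5
#: Probabilities are clamped to [eps, 1-eps] before logs so saturated
#: predictions yield finite losses.
PROB_EPS = 1e-7


@dataclass(frozen=True)
class Detection:
    image_id: str
    box: Box
    lesion: LesionClass
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float


@dataclass
class GridTarget:
    """One grid of YOLO targets/predictions: S² cells × B box slots.

    ``obj_indicator`` is the binary I_ij^obj mask (1 when slot j of cell i
    is responsible for an object); class probabilities live per cell.
    """

    obj_indicator: np.ndarray      # (S², B) in {0,1}
    true_confidence: np.ndarray    # (S², B)
    pred_confidence: np.ndarray    # (S², B)
    true_class_prob: np.ndarray    # (S², C)
    pred_class_prob: np.ndarray    # (S², C)

    def __post_init__(self) -> None:
        for name in ("obj_indicator", "true_confidence", "pred_confidence",
                     "true_class_prob", "pred_class_prob"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.obj_indicator.shape != self.true_confidence.shape or \
           self.obj_indicator.shape != self.pred_confidence.shape:
            raise ValueError("confidence arrays must share the (S², B) shape")
        if self.true_class_prob.shape != self.pred_class_prob.shape:
            raise ValueError("class-probability arrays must share the (S², C) shape")
        if self.true_class_prob.shape[0] != self.obj_indicator.shape[0]:
            raise ValueError("class arrays must have S² rows")
        if not np.isin(self.obj_indicator, (0.0, 1.0)).all():
            raise ValueError("obj_indicator must be binary")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 for disjoint boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: IoU minus the enclosing-box slack (A_c − U)/A_c."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    enclosing = (max(a.x_max, b.x_max) - min(a.x_min, b.x_min)) * \
                (max(a.y_max, b.y_max) - min(a.y_min, b.y_min))
    value = inter / union - (enclosing - union) / enclosing
    return value


# ---------------------------------------------------------------------------
# Reference losses
# ---------------------------------------------------------------------------

def _bce(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    p = np.clip(pred, PROB_EPS, 1.0 - PROB_EPS)
    return -(true * np.log(p) + (1.0 - true) * np.log(1.0 - p))


def giou_loss(targets: GridTarget, pred_boxes: Sequence, true_boxes: Sequence) -> float:
    """Box-regression loss: Σ_i Σ_j I_ij^obj · (1 − GIoU(pred, true)).

    ``pred_boxes``/``true_boxes`` are (S², B) nested sequences of Box (or
    None where the indicator is 0); masked slots contribute nothing.
    """
    ind = targets.obj_indicator
    s2, nb = ind.shape
    if len(pred_boxes) != s2 or len(true_boxes) != s2:
        raise ValueError("box grids must have S² rows")
    total = 0.0
    for i in range(s2):
        if len(pred_boxes[i]) != nb or len(true_boxes[i]) != nb:
            raise ValueError("box grids must have B columns")
        for j in range(nb):
            if ind[i, j]:
                total += 1.0 - giou(pred_boxes[i][j], true_boxes[i][j])
    return total


def confidence_loss(
    targets: GridTarget, lambda_noobj: float = DEFAULT_LAMBDA_NOOBJ
) -> float:
    """Confidence BCE over object slots plus λ_noobj times the no-object BCE."""
    bce = _bce(targets.true_confidence, targets.pred_confidence)
    obj = targets.obj_indicator
    return float((bce * obj).sum() + lambda_noobj * (bce * (1.0 - obj)).sum())


def classification_loss(targets: GridTarget) -> float:
    """Per-class BCE summed over cells that contain at least one object."""
    cell_has_obj = targets.obj_indicator.max(axis=1)
    bce = _bce(targets.true_class_prob, targets.pred_class_prob)
    return float((bce.sum(axis=1) * cell_has_obj).sum())


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------

def _sort_by_confidence(dets: Sequence[Detection]) -> list[Detection]:
    # stable: ties keep input order
    return sorted(dets, key=lambda d: -d.confidence)


def match_detections(
    dets: Sequence[Detection],
    truths: Sequence[Annotation],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> dict[LesionClass, ConfusionCounts]:
    """Greedy one-to-one matching (PASCAL protocol) → per-class confusion.

    Per image and class, detections are taken in descending confidence;
    each claims the unmatched same-class ground-truth box of highest
    IoU ≥ threshold (TP) or becomes an FP; leftover truths are FN.  TN is
    image-level: images with no truth and no detection of the class.
    """
    truth_by_image = {ann.image_id: ann for ann in truths}
    for det in dets:
        if det.image_id not in truth_by_image:
            raise KeyError(f"detection references unknown image id {det.image_id!r}")
    counts = {c: ConfusionCounts() for c in LesionClass}
    dets_by_image: dict[str, list[Detection]] = {i: [] for i in truth_by_image}
    for det in dets:
        dets_by_image[det.image_id].append(det)
    for image_id, ann in truth_by_image.items():
        for lesion in LesionClass:
            gt_boxes = [b for b, c in ann.boxes if c is lesion]
            cls_dets = [d for d in dets_by_image[image_id] if d.lesion is lesion]
            if not gt_boxes and not cls_dets:
                counts[lesion].tn += 1
                continue
            matched = [False] * len(gt_boxes)
            for det in _sort_by_confidence(cls_dets):
                best, best_iou = -1, iou_threshold
                for k, gt in enumerate(gt_boxes):
                    if matched[k]:
                        continue
                    v = iou(det.box, gt)
                    if v >= best_iou:
                        best, best_iou = k, v
                if best >= 0:
                    matched[best] = True
                    counts[lesion].tp += 1
                else:
                    counts[lesion].fp += 1
            counts[lesion].fn += matched.count(False)
    return counts


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Precision, recall, specificity, accuracy, F1 with 0/0 → 0 conventions."""

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.debug("0/0 in %s; defined as 0", name)
            return 0.0
        return num / den

    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    accuracy = ratio(counts.tp + counts.tn,
                     counts.tp + counts.tn + counts.fp + counts.fn, "accuracy")
    return ClassMetrics(precision, recall, specificity, accuracy,
                        f1_score(precision, recall))


def average_precision(
    dets: Sequence[Detection],
    truths: Sequence[Annotation],
    lesion: LesionClass,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> float:
    """All-point AP: exact area under the precision–recall step curve.

    The confidence-sorted detection list is swept once; at each detection
    the recall increment is multiplied by the precision at that point (no
    11-point sampling, no monotone envelope).
    """
    truth_by_image = {ann.image_id: ann for ann in truths}
    n_pos = sum(
        sum(1 for _, c in ann.boxes if c is lesion) for ann in truths
    )
    if n_pos == 0:
        raise ValueError(
            f"no ground truth of class {lesion.label}; AP undefined"
        )
    cls_dets = [d for d in dets if d.lesion is lesion]
    for det in cls_dets:
        if det.image_id not in truth_by_image:
            raise KeyError(f"detection references unknown image id {det.image_id!r}")
    matched: dict[str, list[bool]] = {
        i: [False] * sum(1 for _, c in a.boxes if c is lesion)
        for i, a in truth_by_image.items()
    }
    gt_boxes: dict[str, list[Box]] = {
        i: [b for b, c in a.boxes if c is lesion] for i, a in truth_by_image.items()
    }
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    for det in _sort_by_confidence(cls_dets):
        boxes = gt_boxes[det.image_id]
        flags = matched[det.image_id]
        best, best_iou = -1, iou_threshold
        for k, gt in enumerate(boxes):
            if flags[k]:
                continue
            v = iou(det.box, gt)
            if v >= best_iou:
                best, best_iou = k, v
        if best >= 0:
            flags[best] = True
            tp += 1
        else:
            fp += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


@dataclass
class MetricsReport:
    """Per-class summary metrics plus mAP50, mirroring a results table."""

    per_class: dict[LesionClass, ClassMetrics]
    ap50: dict[LesionClass, float]
    counts: dict[LesionClass, ConfusionCounts]
    map50: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lesion in LesionClass:
            m = self.per_class[lesion]
            rows.append(
                {
                    "class": lesion.label,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "ap50": self.ap50.get(lesion, float("nan")),
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "tn_definition": "image-level: images with neither ground truth "
                             "nor detections of the class",
            "map50": self.map50,
            "classes": {
                lesion.label: {
                    "counts": vars(self.counts[lesion]),
                    "metrics": vars(self.per_class[lesion]),
                    "ap50": self.ap50.get(lesion),
                }
                for lesion in LesionClass
            },
        }
        return json.dumps(payload, indent=2)


def evaluate(
    dets: Sequence[Detection],
    truths: Sequence[Annotation],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MetricsReport:
    """Full evaluation: matching, per-class metrics, AP50, mAP50.

    Classes absent from the ground truth are skipped for AP (and excluded
    from the mAP mean) rather than scored 0.
    """
    counts = match_detections(dets, truths, iou_threshold)
    per_class = {c: compute_metrics(counts[c]) for c in LesionClass}
    ap50 = {}
    for lesion in LesionClass:
        try:
            ap50[lesion] = average_precision(dets, truths, lesion, iou_threshold)
        except ValueError:
            logger.warning("no ground truth for class %s; AP skipped", lesion.label)
    map50 = float(np.mean(list(ap50.values()))) if ap50 else math.nan
    return MetricsReport(per_class=per_class, ap50=ap50, counts=counts, map50=map50)


# ---------------------------------------------------------------------------
# Detection file I/O
# ---------------------------------------------------------------------------

def read_detections_jsonl(text: str) -> list[Detection]:
    """JSON-lines detections: image_id, class, confidence, box (pixels)."""
    dets = []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        dets.append(
            Detection(
                image_id=rec["image_id"],
                box=Box(*rec["box"]),
                lesion=LesionClass.from_name(str(rec["class"])),
                confidence=float(rec["confidence"]),
            )
        )
    return dets


def write_detections_jsonl(dets: Iterable[Detection]) -> str:
    lines = []
    for d in dets:
        lines.append(json.dumps({
            "image_id": d.image_id,
            "class": d.lesion.code,
            "confidence": d.confidence,
            "box": [d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max],
        }))
    return "\n".join(lines) + ("\n" if lines else "")


def read_detections_yolo_txt(
    text: str, image_id: str, width: int, height: int
) -> list[Detection]:
    """YOLO result txt: ``class conf cx cy w h`` normalized per line."""
    dets = []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        idx = int(parts[0])
        conf = float(parts[1])
        cx, cy, w, h = (float(p) for p in parts[2:6])
        dets.append(
            Detection(
                image_id=image_id,
                box=Box((cx - w / 2) * width, (cy - h / 2) * height,
                        (cx + w / 2) * width, (cy + h / 2) * height),
                lesion=LesionClass.from_index(idx),
                confidence=conf,
            )
        )
    return dets
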