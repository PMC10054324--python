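"""Detector-agnostic post-processing and evaluation.

The detector itself (e.g. a YOLO-family network) is an external producer of
per-frame boxes with class labels and confidence scores; this module owns what
happens after: confidence filtering, class-agnostic non-maximum suppression,
and the standard object-detection evaluation suite — per-class precision /
recall / F1 over a confidence grid, average precision at IoU 0.5, mAP, and a
confusion matrix extended with a background row/column so that missed animals
and spurious boxes are visible alongside cross-class confusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BoundingBox",
    "Detection",
    "EvaluationResult",
    "iou",
    "nms",
    "filter_confidence",
    "evaluate",
    "read_detections_csv",
    "write_detections_csv",
    "read_yolo_detections",
    "DEFAULT_CONFIDENCE_GRID",
]

DEFAULT_CONFIDENCE_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 3)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, upper-left (x1, y1) to bottom-right (x2, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {(self.x1, self.y1, self.x2, self.y2)}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    def corners(self) -> np.ndarray:
        """(4, 2) array in TL, TR, BL, BR order."""
        return np.array([[self.x1, self.y1], [self.x2, self.y1],
                         [self.x1, self.y2], [self.x2, self.y2]])


@dataclass(frozen=True)
class Detection:
    """One detected animal in one camera frame."""

    frame: int
    camera: str  # "left" | "right"
    box: BoundingBox
    label: str
    confidence: float = 1.0
    stream_id: str = "stream0"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def filter_confidence(detections, min_confidence: float):
    """Drop detections below a confidence threshold."""
    return [d for d in detections if d.confidence >= min_confidence]


def nms(detections, iou_threshold: float = 0.6):
    """Class-agnostic greedy non-maximum suppression.

    Detections are visited in order of descending confidence (ties broken by
    input order); a detection is suppressed when its IoU with an already-kept
    box is *greater than* ``iou_threshold`` — boxes overlapping at exactly the
    threshold survive. Intended for the detections of a single frame/camera.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= iou_threshold
               for j in kept):
            kept.append(i)
    kept.sort()
    return [detections[i] for i in kept]


@dataclass
class EvaluationResult:
    """Output of :func:`evaluate`.

    ``confusion`` raw counts have one row/column per class plus a trailing
    background row/column: row = true class, column = predicted class; the
    background column collects missed ground truth (false negatives), the
    background row collects unmatched detections (false positives).
    """

    classes: list
    confusion: np.ndarray            # (n+1, n+1) raw counts
    confusion_row_norm: np.ndarray   # rows normalized to sum 1 (where nonzero)
    confusion_col_norm: np.ndarray   # columns normalized to sum 1
    ap: dict                         # class -> AP@iou_min
    map50: float
    confidence_grid: np.ndarray
    precision: dict                  # class -> array over grid
    recall: dict
    f1: dict
    mean_f1: np.ndarray              # mean over classes per grid point
    best_f1: float
    best_f1_confidence: float


def _greedy_match(dets, gts, iou_min, class_aware, det_used, gt_used):
    """Greedy one-to-one matching by descending confidence; mutates used sets.

    Returns list of (det_idx, gt_idx) pairs.
    """
    pairs = []
    order = sorted((i for i in range(len(dets)) if i not in det_used),
                   key=lambda i: (-dets[i].confidence, i))
    for i in order:
        best_j, best_iou = None, iou_min
        for j, (gbox, glabel) in enumerate(gts):
            if j in gt_used:
                continue
            if class_aware and glabel != dets[i].label:
                continue
            v = iou(dets[i].box, gbox)
            if v >= best_iou and (best_j is None or v > best_iou):
                best_j, best_iou = j, v
        if best_j is not None:
            det_used.add(i)
            gt_used.add(best_j)
            pairs.append((i, best_j))
    return pairs


def _ranked_flags(dets_cls, gt_by_frame, iou_min):
    """Per-class ranked TP/FP flags for PR/AP computation.

    Detections of one class across all frames, sorted by descending
    confidence, greedily matched one-to-one against same-class ground truth of
    their frame. Returns (confidences, tp_flags, n_gt).
    """
    order = sorted(range(len(dets_cls)),
                   key=lambda i: (-dets_cls[i].confidence, i))
    gt_used: dict = {}
    conf = np.empty(len(order))
    tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        d = dets_cls[i]
        conf[rank] = d.confidence
        gts = gt_by_frame.get((d.stream_id, d.frame, d.camera), [])
        used = gt_used.setdefault((d.stream_id, d.frame, d.camera), set())
        best_j, best_iou = None, iou_min
        for j, (gbox, glabel) in enumerate(gts):
            if j in used or glabel != d.label:
                continue
            v = iou(d.box, gbox)
            if v >= iou_min and (best_j is None or v > best_iou):
                best_j, best_iou = j, v
        if best_j is not None:
            used.add(best_j)
            tp[rank] = True
    return conf, tp


def _average_precision(tp: np.ndarray, n_gt: int) -> float:
    """All-point-interpolated AP from ranked TP flags."""
    if n_gt == 0:
        return float("nan")
    if tp.size == 0:
        return 0.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, integrated over recall steps
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def evaluate(ground_truth, detections, classes, iou_min: float = 0.5,
             confidence_grid=None, confusion_confidence: float = 0.25) -> EvaluationResult:
    """Score detections against ground truth.

    Parameters
    ----------
    ground_truth : iterable of Detection (confidence ignored) — the annotations.
    detections : iterable of Detection with confidence scores.
    classes : the class vocabulary; a detection label outside it is an error.
    iou_min : minimum IoU for a true positive (0.5 for the standard mAP@0.5).
    confusion_confidence : score cut-off applied before building the
        confusion matrix (PR/AP use the full score range).

    Matching is greedy by descending confidence and one-to-one per frame.
    The confusion matrix is filled by a class-aware pass first; a second,
    class-agnostic pass over the leftovers attributes cross-class confusion;
    what remains goes to the background row/column.
    """
    classes = list(classes)
    class_idx = {c: i for i, c in enumerate(classes)}
    for d in detections:
        if d.label not in class_idx:
            raise ValueError(f"unknown class label {d.label!r}")
    for g in ground_truth:
        if g.label not in class_idx:
            raise ValueError(f"unknown ground-truth label {g.label!r}")

    gt_by_frame: dict = {}
    for g in ground_truth:
        gt_by_frame.setdefault((g.stream_id, g.frame, g.camera), []).append(
            (g.box, g.label))
    n_gt_cls = {c: 0 for c in classes}
    for g in ground_truth:
        n_gt_cls[g.label] += 1

    # --- PR curves and AP per class ------------------------------------
    grid = DEFAULT_CONFIDENCE_GRID if confidence_grid is None else np.asarray(confidence_grid, dtype=float)
    ap: dict = {}
    precision: dict = {}
    recall: dict = {}
    f1: dict = {}
    for c in classes:
        dets_c = [d for d in detections if d.label == c]
        conf, tp = _ranked_flags(dets_c, {k: v for k, v in gt_by_frame.items()},
                                 iou_min)
        n_gt = n_gt_cls[c]
        ap[c] = _average_precision(tp, n_gt)
        # threshold sweep from the ranked flags
        n_det_ge = np.searchsorted(-conf, -grid, side="right")
        tp_cum = np.concatenate([[0], np.cumsum(tp)])
        tp_ge = tp_cum[n_det_ge]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_det_ge > 0, tp_ge / np.maximum(n_det_ge, 1), 1.0)
            r = tp_ge / n_gt if n_gt > 0 else np.full_like(grid, np.nan)
            f = np.where((p + r) > 0, 2 * p * r / (p + r), 0.0)
        precision[c], recall[c], f1[c] = p, r, f

    valid = [c for c in classes if n_gt_cls[c] > 0]
    map50 = float(np.mean([ap[c] for c in valid])) if valid else float("nan")
    if valid:
        mean_f1 = np.mean([f1[c] for c in valid], axis=0)
        best_idx = int(np.argmax(mean_f1))
        best_f1 = float(mean_f1[best_idx])
        best_conf = float(grid[best_idx])
    else:
        mean_f1 = np.full_like(grid, np.nan)
        best_f1, best_conf = float("nan"), float("nan")

    # --- confusion matrix ----------------------------------------------
    n = len(classes)
    confusion = np.zeros((n + 1, n + 1), dtype=int)
    dets_by_frame: dict = {}
    for d in detections:
        if d.confidence >= confusion_confidence:
            dets_by_frame.setdefault((d.stream_id, d.frame, d.camera), []).append(d)
    frames = set(gt_by_frame) | set(dets_by_frame)
    for key in frames:
        dets = dets_by_frame.get(key, [])
        gts = gt_by_frame.get(key, [])
        det_used: set = set()
        gt_used: set = set()
        for i, j in _greedy_match(dets, gts, iou_min, True, det_used, gt_used):
            k = class_idx[dets[i].label]
            confusion[k, k] += 1
        for i, j in _greedy_match(dets, gts, iou_min, False, det_used, gt_used):
            confusion[class_idx[gts[j][1]], class_idx[dets[i].label]] += 1
        for j, (gbox, glabel) in enumerate(gts):
            if j not in gt_used:
                confusion[class_idx[glabel], n] += 1  # missed -> background col
        for i, d in enumerate(dets):
            if i not in det_used:
                confusion[n, class_idx[d.label]] += 1  # spurious -> background row

    with np.errstate(invalid="ignore", divide="ignore"):
        row_sum = confusion.sum(axis=1, keepdims=True)
        col_sum = confusion.sum(axis=0, keepdims=True)
        row_norm = np.where(row_sum > 0, confusion / np.maximum(row_sum, 1), 0.0)
        col_norm = np.where(col_sum > 0, confusion / np.maximum(col_sum, 1), 0.0)

    return EvaluationResult(classes=classes, confusion=confusion,
                            confusion_row_norm=row_norm,
                            confusion_col_norm=col_norm, ap=ap, map50=map50,
                            confidence_grid=grid, precision=precision,
                            recall=recall, f1=f1, mean_f1=mean_f1,
                            best_f1=best_f1, best_f1_confidence=best_conf)


# ---------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = ["stream_id", "frame", "camera", "x1", "y1", "x2", "y2",
                "class", "confidence"]


def write_detections_csv(detections, path) -> None:
    rows = [{"stream_id": d.stream_id, "frame": d.frame, "camera": d.camera,
             "x1": d.box.x1, "y1": d.box.y1, "x2": d.box.x2, "y2": d.box.y2,
             "class": d.label, "confidence": d.confidence}
            for d in detections]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns: {sorted(missing)}")
    return [Detection(frame=int(r["frame"]), camera=str(r["camera"]),
                      box=BoundingBox(float(r["x1"]), float(r["y1"]),
                                      float(r["x2"]), float(r["y2"])),
                      label=str(r["class"]), confidence=float(r["confidence"]),
                      stream_id=str(r["stream_id"]))
            for r in df.to_dict("records")]


def read_yolo_detections(txt_path, image_size, frame: int, camera: str,
                         classes, stream_id: str = "stream0") -> list:
    """Read one YOLO-format per-image text file.

    Each line is ``class_idx cx cy w h [confidence]`` with coordinates
    normalized by the image size given as ``(width, height)``.
    """
    w_img, h_img = image_size
    out = []
    for line in Path(txt_path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        ci, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        box = BoundingBox((cx - w / 2) * w_img, (cy - h / 2) * h_img,
                          (cx + w / 2) * w_img, (cy + h / 2) * h_img)
        out.append(Detection(frame=frame, camera=camera, box=box,
                             label=classes[ci], confidence=conf,
                             stream_id=stream_id))
    return out
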