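"""Bounding boxes, IoU, per-class NMS, detector ensembling, and a reference detector.

The detector interface is a contract, not an architecture: anything callable as
``detector(image) -> list[BoundingBox]`` with a ``descriptor`` attribute plugs
into the pipeline. Trained single-shot detectors fulfil it in production; the
bundled :class:`BlobDetector` (intensity threshold + connected components)
fulfils it at desk scale, and :class:`YoloFileDetector` replays externally
computed predictions from YOLO-format text files bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .imaging import BreastExam, MammogramView, standardize_orientation

logger = logging.getLogger("dvscreen.detect")

#: The six finding classes the detectors report.
CLASS_NAMES = (
    "suspicious_mass",
    "lymph_node",
    "calcification",
    "architectural_distortion",
    "skin_thickening",
    "nipple_retraction",
)

#: Default IoU threshold for greedy suppression (common detector default; not
#: derived from any reported experiment).
DEFAULT_NMS_IOU = 0.45


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based half-open, origin top-left, x = column."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_name: str = "suspicious_mass"
    objectness: float = 1.0
    source_model: str = ""

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})")
        if not 0.0 <= self.objectness <= 1.0:
            raise ValueError(f"objectness must be in [0,1], got {self.objectness}")
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@runtime_checkable
class DetectorContract(Protocol):
    """A detector maps a [0,1] intensity array to in-image bounding boxes."""

    descriptor: str

    def __call__(self, image: np.ndarray) -> list[BoundingBox]: ...


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _greedy_order(boxes: Sequence[BoundingBox]) -> list[BoundingBox]:
    # Descending objectness; deterministic tie-break on lower (x_min, y_min).
    return sorted(boxes, key=lambda b: (-b.objectness, b.x_min, b.y_min, b.x_max, b.y_max))


def nms(boxes: Sequence[BoundingBox], iou_threshold: float = DEFAULT_NMS_IOU) -> list[BoundingBox]:
    """Greedy per-class non-maximum suppression.

    Within each class, repeatedly keep the highest-objectness box and drop the
    remaining boxes of that class overlapping it with IoU >= ``iou_threshold``.
    Suppression never crosses classes, preserving e.g. the mass vs lymph-node
    distinction. Survivors are returned sorted by descending objectness.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must be in (0,1), got {iou_threshold}")
    survivors: list[BoundingBox] = []
    classes = sorted({b.class_name for b in boxes})
    for cls in classes:
        pending = _greedy_order([b for b in boxes if b.class_name == cls])
        while pending:
            keep = pending.pop(0)
            survivors.append(keep)
            pending = [b for b in pending if iou(keep, b) < iou_threshold]
    return _greedy_order(survivors)


def ensemble_detections(per_model_boxes: Sequence[Sequence[BoundingBox]],
                        iou_threshold: float = DEFAULT_NMS_IOU) -> list[BoundingBox]:
    """Fuse several models' predictions: pool all boxes, then apply NMS.

    Where models agree on a region, the highest-objectness box wins and keeps
    its ``source_model`` tag; disjoint predictions pass through untouched.
    """
    if len(per_model_boxes) < 1:
        raise ValueError("ensemble_detections needs at least one model's output")
    pooled = [b for model_boxes in per_model_boxes for b in model_boxes]
    return nms(pooled, iou_threshold)


def _flip_box_x(b: BoundingBox, width: int) -> BoundingBox:
    return replace(b, x_min=width - b.x_max, x_max=width - b.x_min)


def detect_exam(detector: DetectorContract, exam: BreastExam) -> tuple[list[BoundingBox], list[BoundingBox]]:
    """Run a detector on both views of a breast.

    Each view is standardized (right breasts mirrored) before detection, and
    detected boxes are mapped back to the original image coordinates so that
    overlays render on the source pixels.
    """
    results: list[list[BoundingBox]] = []
    for v in (exam.cc, exam.mlo):
        sv = standardize_orientation(v)
        try:
            boxes = detector(sv.pixels)
        except Exception as exc:
            raise RuntimeError(f"detector {getattr(detector, 'descriptor', detector)!r} failed "
                               f"on {v.study_id}/{v.laterality}-{v.view}") from exc
        if v.laterality == "R":
            width = v.pixels.shape[1]
            boxes = [_flip_box_x(b, width) for b in boxes]
        results.append(boxes)
    return results[0], results[1]


def max_objectness(boxes_cc: Sequence[BoundingBox], boxes_mlo: Sequence[BoundingBox],
                   class_name: str = "suspicious_mass") -> float:
    """Breast-level score: max objectness of ``class_name`` over both views, 0 if absent.

    The max (rather than the mean) keeps the OR-like sensitivity of the
    screening rule: a confident finding in either projection is enough.
    """
    scores = [b.objectness for b in (*boxes_cc, *boxes_mlo) if b.class_name == class_name]
    return max(scores) if scores else 0.0


@dataclass
class BlobDetector:
    """Reference intensity-blob detector for desk-scale runs.

    Thresholds the image at the larger of an intensity quantile and an absolute
    floor, labels connected components, and emits one box per component above a
    minimum area. The floor is the working threshold on calibrated [0,1]
    images; the quantile is a guard that keeps globally bright images from
    saturating the mask. Boxes can optionally be dilated by ``box_dilation``
    of their own width/height per side (clamped to the image) when the
    downstream consumer wants generous overlays. Objectness is the component's
    mean intensity, which for [0,1] images is itself a valid confidence.
    Entirely deterministic.
    """

    quantile: float = 0.90
    intensity_floor: float = 0.55
    min_area: int = 20
    box_dilation: float = 0.0
    class_name: str = "suspicious_mass"
    descriptor: str = "blob:quantile-threshold+connected-components"

    def __call__(self, image: np.ndarray) -> list[BoundingBox]:
        img = np.asarray(image, dtype=float)
        thr = max(float(np.quantile(img, self.quantile)), self.intensity_floor)
        mask = img > thr
        if not mask.any():
            return []
        labels, n = ndimage.label(mask)
        boxes: list[BoundingBox] = []
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            component = img[sl]
            region_mask = mask[sl]
            area = int(region_mask.sum())
            if area < self.min_area:
                continue
            y0, y1 = sl[0].start, sl[0].stop
            x0, x1 = sl[1].start, sl[1].stop
            dx, dy = self.box_dilation * (x1 - x0), self.box_dilation * (y1 - y0)
            x0, x1 = max(0.0, x0 - dx), min(float(img.shape[1]), x1 + dx)
            y0, y1 = max(0.0, y0 - dy), min(float(img.shape[0]), y1 + dy)
            score = float(np.clip(component[region_mask].mean(), 0.0, 1.0))
            boxes.append(BoundingBox(x_min=float(x0), y_min=float(y0),
                                     x_max=float(x1), y_max=float(y1),
                                     class_name=self.class_name, objectness=score,
                                     source_model=self.descriptor))
        return _greedy_order(boxes)


def blob_detect(image: np.ndarray, **kwargs) -> list[BoundingBox]:
    """Functional wrapper over :class:`BlobDetector` with its defaults."""
    return BlobDetector(**kwargs)(image)


@dataclass
class YoloFileDetector:
    """Replays external YOLO-format predictions (``class cx cy w h conf``) from disk.

    ``path_for`` maps an image shape-keyed request to the prediction file; in
    practice you construct one detector per image via :func:`read_yolo_predictions`
    or use this class through the CLI, which pairs files by stem.
    """

    directory: Path
    stem: str
    class_names: Sequence[str] = CLASS_NAMES
    descriptor: str = "yolo-files"

    def __call__(self, image: np.ndarray) -> list[BoundingBox]:
        path = Path(self.directory) / f"{self.stem}.txt"
        if not path.exists():
            return []
        return read_yolo_predictions(path, image.shape, self.class_names,
                                     source_model=self.descriptor)


def read_yolo_predictions(path: str | Path, image_shape: tuple[int, int],
                          class_names: Sequence[str] = CLASS_NAMES,
                          source_model: str = "yolo-files") -> list[BoundingBox]:
    """Parse a YOLO prediction file: one ``class cx cy w h [conf]`` line per box.

    Coordinates are normalized to [0,1] and are denormalized against
    ``image_shape`` = (height, width); a missing confidence defaults to 1.
    """
    h, w = image_shape
    boxes: list[BoundingBox] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls_idx = int(parts[0])
        cx, cy, bw, bh = (float(p) for p in parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        boxes.append(BoundingBox(
            x_min=(cx - bw / 2) * w, y_min=(cy - bh / 2) * h,
            x_max=(cx + bw / 2) * w, y_max=(cy + bh / 2) * h,
            class_name=class_names[cls_idx], objectness=conf, source_model=source_model))
    return boxes


def dump_detections(path: str | Path, view: str, boxes: Sequence[BoundingBox]) -> None:
    """Append detections for one view to a JSON-lines dump."""
    with open(path, "a") as fh:
        for b in boxes:
            fh.write(json.dumps({"view": view, "class": b.class_name,
                                 "box": list(b.as_tuple()), "objectness": b.objectness,
                                 "source_model": b.source_model}) + "\n")
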