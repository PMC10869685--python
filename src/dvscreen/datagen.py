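"""Deterministic synthetic mammogram generator with ground-truth labels and boxes.

Every downstream stage — loading, the dual-view classifier, detection, triage
and evaluation — is testable against cohorts produced here, with no external
data. A generated breast is a bright half-elliptical tissue region on a dark
background; MLO views additionally carry a triangular pectoral-muscle wedge in
the upper chest-wall corner. Abnormal breasts contain bright Gaussian-profile
elliptical blobs standing in for masses; the same latent abnormality drives
both projections, with blob positions sharing their radial distance from the
chest wall across views (independent angular jitter), the way a physical mass
reappears in both projections without a true 3-D model. Right-laterality
breasts are rendered horizontally mirrored relative to left ones.

The generator emulates: paired views sharing one abnormality state, mass-like
soft-edged blobs with exact ground-truth boxes, BI-RADS categories consistent
with the binary label, and laterality-dependent orientation. It does not
emulate tissue texture, density categories, compression artifacts or burned-in
labels, so results on it bound plumbing correctness, not clinical performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .detect import CLASS_NAMES, BoundingBox
from .imaging import ABNORMAL, NORMAL, BreastExam, MammogramView

#: Extra small, high-intensity finding classes the generator can plant to
#: exercise the multi-class detector path.
EXTRA_CLASSES = ("lymph_node", "calcification")


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic cohort; identical (params, seed) → bit-identical output.

    Intensities are on the [0,1] scale of the emitted 8-bit PNGs. Defaults give
    a high-contrast, clearly separable cohort: blob peaks (~0.9) stand well
    above breast tissue (0.35) and the pectoral wedge (0.45).
    """

    image_size: int = 128
    abnormal_fraction: float = 0.5
    blob_count_range: tuple[int, int] = (1, 3)
    blob_radius_range: tuple[float, float] = (6.0, 14.0)
    noise_sd: float = 0.03
    seed: int = 0
    background: float = 0.05
    breast_intensity: float = 0.35
    pectoral_intensity: float = 0.45
    blob_amplitude: float = 0.55
    extra_class_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16 pixels")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must be in [0,1]")
        lo, hi = self.blob_count_range
        if not (0 < lo <= hi):
            raise ValueError("blob_count_range must satisfy 0 < min <= max")
        rlo, rhi = self.blob_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("blob_radius_range must satisfy 0 < min <= max")
        if rhi >= self.image_size / 2:
            raise ValueError("blob radii must be < image_size/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.extra_class_prob <= 1.0:
            raise ValueError("extra_class_prob must be in [0,1]")


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth for one generated breast."""

    label: int
    boxes_cc: tuple[BoundingBox, ...]
    boxes_mlo: tuple[BoundingBox, ...]
    birads: int

    def __post_init__(self) -> None:
        if self.label == ABNORMAL and not (self.boxes_cc and self.boxes_mlo):
            raise ValueError("abnormal breasts must carry boxes in both views")
        if self.label == NORMAL and (self.boxes_cc or self.boxes_mlo):
            raise ValueError("normal breasts must carry no boxes")
        if (self.birads == 1) != (self.label == NORMAL):
            raise ValueError("birads must be 1 iff the breast is normal")


# Breast half-ellipse geometry, as fractions of the image side. The chest wall
# is the left image edge in canonical (left-laterality) orientation.
_BREAST_RX, _BREAST_RY = 0.72, 0.42
# Pectoral wedge extent in MLO views (fractions of the side).
_PECT_X, _PECT_Y = 0.30, 0.42


def _canvas(params: SynthParams, view: str) -> tuple[np.ndarray, np.ndarray]:
    """Canonical-orientation background: breast ellipse (+ MLO pectoral wedge)."""
    s = params.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cy = s / 2.0
    rx, ry = _BREAST_RX * s, _BREAST_RY * s
    breast = (xx / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    img = np.full((s, s), params.background, dtype=float)
    img[breast] = params.breast_intensity
    if view == "MLO":
        wedge = xx / (_PECT_X * s) + yy / (_PECT_Y * s) < 1.0
        img[wedge] = params.pectoral_intensity
    return img, breast


def _blob_center(params: SynthParams, t: float, angle: float, radius: float) -> tuple[float, float]:
    """Center a blob inside the breast ellipse at shared radial fraction ``t``."""
    s = params.image_size
    cy = s / 2.0
    # Shrink the ellipse so the full ground-truth box stays inside both the
    # breast region and the image.
    margin = radius + 2.0
    rx = max(_BREAST_RX * s - margin, margin)
    ry = max(_BREAST_RY * s - margin, margin)
    cx = t * rx * math.cos(angle)
    cyy = cy + t * ry * math.sin(angle)
    cx = float(np.clip(cx, margin, s - margin))
    cyy = float(np.clip(cyy, margin, s - margin))
    return cx, cyy


def _paint_blob(img: np.ndarray, cx: float, cy: float, radius: float, amplitude: float) -> None:
    s = img.shape[0]
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    sigma = radius / 2.0
    img += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma ** 2))


def _box_from_blob(cx: float, cy: float, radius: float, size: int,
                   class_name: str) -> BoundingBox:
    x0, x1 = max(0.0, cx - radius), min(float(size), cx + radius)
    y0, y1 = max(0.0, cy - radius), min(float(size), cy + radius)
    return BoundingBox(x_min=round(x0), y_min=round(y0), x_max=round(x1), y_max=round(y1),
                       class_name=class_name, objectness=1.0, source_model="ground_truth")


def generate_exam(params: SynthParams, study_id: str, laterality: str,
                  rng: np.random.Generator | int | None = None) -> tuple[BreastExam, GroundTruth]:
    """Generate one breast: a CC and an MLO view sharing a latent abnormality state.

    Abnormal breasts (probability ``abnormal_fraction``) receive the same blob
    count in both views; each blob shares its radial position from the chest
    wall across views with independent angular jitter. Right-laterality output
    is mirrored horizontally, boxes included.
    """
    if laterality not in ("L", "R"):
        raise ValueError(f"laterality must be 'L' or 'R', got {laterality!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)

    abnormal = rng.random() < params.abnormal_fraction
    birads = int(rng.integers(2, 6)) if abnormal else 1

    blobs: list[tuple[float, float, str]] = []  # (radial fraction, radius, class)
    if abnormal:
        lo, hi = params.blob_count_range
        n_blobs = int(rng.integers(lo, hi + 1))
        rlo, rhi = params.blob_radius_range
        for _ in range(n_blobs):
            t = rng.uniform(0.15, 0.70)
            radius = rng.uniform(rlo, rhi)
            blobs.append((t, radius, "suspicious_mass"))
        if rng.random() < params.extra_class_prob:
            cls = EXTRA_CLASSES[int(rng.integers(0, len(EXTRA_CLASSES)))]
            blobs.append((rng.uniform(0.2, 0.6), rng.uniform(2.5, 4.0), cls))

    views: dict[str, MammogramView] = {}
    boxes: dict[str, tuple[BoundingBox, ...]] = {}
    for view in ("CC", "MLO"):
        img, _ = _canvas(params, view)
        view_boxes: list[BoundingBox] = []
        for t, radius, cls in blobs:
            angle = rng.uniform(-0.6, 0.6)
            cx, cy = _blob_center(params, t, angle, radius)
            _paint_blob(img, cx, cy, radius, params.blob_amplitude)
            view_boxes.append(_box_from_blob(cx, cy, radius, params.image_size, cls))
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        if laterality == "R":
            img = np.fliplr(img)
            w = params.image_size
            view_boxes = [BoundingBox(x_min=w - b.x_max, y_min=b.y_min,
                                      x_max=w - b.x_min, y_max=b.y_max,
                                      class_name=b.class_name, objectness=b.objectness,
                                      source_model=b.source_model) for b in view_boxes]
        # Quantize like the PNG writer so in-memory and on-disk cohorts agree.
        img = np.round(img * 255.0) / 255.0
        views[view] = MammogramView(pixels=img, laterality=laterality, view=view,
                                    study_id=study_id)
        boxes[view] = tuple(view_boxes)

    label = ABNORMAL if abnormal else NORMAL
    exam = BreastExam(cc=views["CC"], mlo=views["MLO"], laterality=laterality,
                      label=label, birads=birads)
    gt = GroundTruth(label=label, boxes_cc=boxes["CC"], boxes_mlo=boxes["MLO"], birads=birads)
    return exam, gt


def write_yolo_annotations(boxes: Sequence[BoundingBox], image_size: int | tuple[int, int],
                           path: str | Path,
                           class_names: Sequence[str] = CLASS_NAMES) -> None:
    """Write one normalized ``class cx cy w h`` line per box (YOLO annotation format)."""
    if isinstance(image_size, int):
        h = w = image_size
    else:
        h, w = image_size
    lines = []
    for b in boxes:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
            raise ValueError(f"box {b.as_tuple()} exceeds the {h}x{w} image")
        cx = (b.x_min + b.x_max) / 2.0 / w
        cy = (b.y_min + b.y_max) / 2.0 / h
        bw = (b.x_max - b.x_min) / w
        bh = (b.y_max - b.y_min) / h
        lines.append(f"{class_names.index(b.class_name)} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_annotations(path: str | Path, image_size: int | tuple[int, int],
                          class_names: Sequence[str] = CLASS_NAMES) -> list[BoundingBox]:
    """Inverse of :func:`write_yolo_annotations`; round-trips pixel boxes to <0.5 px."""
    if isinstance(image_size, int):
        h = w = image_size
    else:
        h, w = image_size
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        idx = int(parts[0])
        cx, cy, bw, bh = (float(p) for p in parts[1:5])
        boxes.append(BoundingBox(x_min=(cx - bw / 2) * w, y_min=(cy - bh / 2) * h,
                                 x_max=(cx + bw / 2) * w, y_max=(cy + bh / 2) * h,
                                 class_name=class_names[idx], objectness=1.0,
                                 source_model="annotation"))
    return boxes


def _save_png(img: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(img * 255.0).astype(np.uint8), mode="L").save(path)


def generate_cohort(params: SynthParams, n_studies: int, out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort: 4 PNGs per study (L/R x CC/MLO), YOLO annotation
    files, and a ``manifest.csv`` (study_id, laterality, view, path, birads, label).

    Returns the manifest as a DataFrame. Deterministic in (params, n_studies):
    one generator seeded with ``params.seed`` drives the whole cohort.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(n_studies):
        study_id = f"S{i:05d}"
        for lat in ("L", "R"):
            exam, gt = generate_exam(params, study_id, lat, rng)
            for view, mv, boxes in (("CC", exam.cc, gt.boxes_cc), ("MLO", exam.mlo, gt.boxes_mlo)):
                stem = f"{study_id}_{lat}_{view}"
                _save_png(mv.pixels, out_dir / f"{stem}.png")
                write_yolo_annotations(boxes, params.image_size, out_dir / f"{stem}.txt")
                rows.append({"study_id": study_id, "laterality": lat, "view": view,
                             "path": f"{stem}.png", "birads": gt.birads, "label": gt.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_exams_in_memory(params: SynthParams, n_studies: int
                             ) -> list[tuple[BreastExam, GroundTruth]]:
    """Generate a cohort without touching disk; same stream as :func:`generate_cohort`."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng = np.random.default_rng(params.seed)
    out = []
    for i in range(n_studies):
        study_id = f"S{i:05d}"
        for lat in ("L", "R"):
            out.append(generate_exam(params, study_id, lat, rng))
    return out
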