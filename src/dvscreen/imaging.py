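"""Image and manifest loading, orientation standardization, BI-RADS label mapping.

Pixel-coordinate convention used everywhere in this package: 0-based, half-open,
origin at the top-left corner, ``x`` indexes columns and ``y`` indexes rows.

After :func:`standardize_orientation` the chest wall sits on the *left* edge of
the image regardless of laterality: right-laterality views are mirrored
horizontally so that both breasts share one canonical orientation before they
reach the classifier or a detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("dvscreen.imaging")

LATERALITIES = ("L", "R")
VIEWS = ("CC", "MLO")

#: BI-RADS categories 1 (negative) .. 6 (biopsy-proven malignancy)
BIRADS_RANGE = (1, 6)

NORMAL, ABNORMAL = 0, 1


class FormatError(ValueError):
    """Raised when an image file cannot be read as a grayscale mammogram."""


class SchemaError(ValueError):
    """Raised when a manifest is missing required columns."""


@dataclass(frozen=True)
class MammogramView:
    """One grayscale mammographic projection plus its acquisition metadata.

    ``pixels`` is a 2-D float array scaled to [0, 1]. ``standardized`` records
    whether the view has passed through :func:`standardize_orientation`.
    """

    pixels: np.ndarray
    laterality: str
    view: str
    study_id: str
    source_path: str | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        object.__setattr__(self, "pixels", px)
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BreastExam:
    """A CC+MLO pair for a single breast, the unit the screening system judges."""

    cc: MammogramView
    mlo: MammogramView
    laterality: str
    label: int | None = None
    birads: int | None = None

    def __post_init__(self) -> None:
        if self.cc.view != "CC" or self.mlo.view != "MLO":
            raise ValueError("BreastExam requires cc.view == 'CC' and mlo.view == 'MLO'")
        if not (self.cc.laterality == self.mlo.laterality == self.laterality):
            raise ValueError("both views must share the exam laterality")
        if self.cc.study_id != self.mlo.study_id:
            raise ValueError("both views must share a study_id")
        if self.label is not None and self.label not in (NORMAL, ABNORMAL):
            raise ValueError("label must be 0 (normal) or 1 (abnormal)")

    @property
    def study_id(self) -> str:
        return self.cc.study_id


def load_view(path: str | Path, laterality: str, view: str, study_id: str) -> MammogramView:
    """Read a grayscale PNG or single-frame DICOM and scale intensities to [0, 1].

    PNG pixels are divided by the dtype maximum (255 for 8-bit); DICOM pixels
    are divided by the per-image maximum, which is robust to vendor-specific
    bit depths. An all-zero image stays all-zero.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        arr = _read_dicom(path)
    else:
        arr = _read_png(path)
    return MammogramView(pixels=arr, laterality=laterality, view=view,
                         study_id=study_id, source_path=str(path))


def _read_png(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("I") if im.mode in ("I;16", "I") else im.convert("L")
            arr = np.asarray(im, dtype=float)
    except Exception as exc:  # pillow raises a zoo of error types
        raise FormatError(f"cannot read {path} as grayscale PNG: {exc}") from exc
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot read {path} as DICOM: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame grayscale DICOM, got shape {arr.shape}")
    arr = arr.astype(float)
    peak = arr.max()
    return arr / peak if peak > 0 else arr


def standardize_orientation(v: MammogramView) -> MammogramView:
    """Mirror right-laterality views horizontally; left views pass through.

    Mirroring maps the chest wall of an R view onto the left image edge so the
    classifier sees one canonical orientation. The operation is an involution
    on the pixel content of R views and the identity on L views.
    """
    if v.laterality == "R":
        return replace(v, pixels=np.fliplr(v.pixels), standardized=True)
    return replace(v, standardized=True)


def birads_to_label(birads: int) -> int:
    """Map a BI-RADS category to the binary screening label.

    Category 1 (negative, no abnormal findings) maps to normal; categories 2-6
    map to abnormal.
    """
    birads = int(birads)
    lo, hi = BIRADS_RANGE
    if not lo <= birads <= hi:
        raise ValueError(f"BI-RADS category must be in {lo}..{hi}, got {birads}")
    return NORMAL if birads == 1 else ABNORMAL


MANIFEST_COLUMNS = ("study_id", "laterality", "view", "path")


def read_manifest(csv_path: str | Path, image_root: str | Path | None = None) -> list[BreastExam]:
    """Assemble per-breast CC/MLO exams from a cohort manifest CSV.

    Rows are grouped by ``(study_id, laterality)``; a breast missing either its
    CC or its MLO view is excluded with a logged warning. The binary label is
    taken from a ``label`` column when present, otherwise derived from
    ``birads`` via :func:`birads_to_label`.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype={"study_id": str, "laterality": str, "view": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {csv_path} is missing columns: {missing}")
    if "label" not in df.columns and "birads" not in df.columns:
        raise SchemaError(f"manifest {csv_path} needs a 'label' or a 'birads' column")

    root = Path(image_root) if image_root is not None else csv_path.parent
    exams: list[BreastExam] = []
    n_excluded = 0
    for (study_id, lat), grp in df.groupby(["study_id", "laterality"], sort=True):
        views = {row["view"]: row for _, row in grp.iterrows()}
        if "CC" not in views or "MLO" not in views:
            n_excluded += 1
            logger.warning("excluding breast %s/%s: missing %s view", study_id, lat,
                           "CC" if "CC" not in views else "MLO")
            continue
        row = views["CC"]
        if "label" in df.columns and not pd.isna(row.get("label")):
            label = int(row["label"])
        else:
            label = birads_to_label(int(row["birads"]))
        birads = int(row["birads"]) if "birads" in df.columns and not pd.isna(row["birads"]) else None
        cc = load_view(root / str(views["CC"]["path"]), lat, "CC", study_id)
        mlo = load_view(root / str(views["MLO"]["path"]), lat, "MLO", study_id)
        exams.append(BreastExam(cc=cc, mlo=mlo, laterality=lat, label=label, birads=birads))
    if n_excluded:
        logger.warning("excluded %d incomplete breast(s) from %s", n_excluded, csv_path)
    return exams


def resize_for_model(v: MammogramView, side: int) -> np.ndarray:
    """Resize a standardized view to a ``side``x``side`` square for the classifier.

    Aspect ratio is preserved: the image is scaled so its longer edge equals
    ``side`` and the remainder is zero-padded on the bottom and on the right —
    the side opposite the chest wall in canonical orientation — so breast
    tissue stays anchored to the top-left corner.
    """
    if side < 8:
        raise ValueError(f"target side must be >= 8, got {side}")
    if not v.standardized:
        raise ValueError("resize_for_model expects a standardized view")
    arr = v.pixels
    h, w = arr.shape
    s = side / max(h, w)
    nh, nw = max(1, round(h * s)), max(1, round(w * s))
    if (nh, nw) != (h, w):
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        arr = np.asarray(im.resize((nw, nh), Image.BILINEAR), dtype=float)
        arr = np.clip(arr, 0.0, 1.0)
    out = np.zeros((side, side), dtype=float)
    out[:nh, :nw] = arr
    return out
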