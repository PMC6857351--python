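"""Shared geometric and image types, box arithmetic, and annotation I/O.

Conventions used throughout the package:

* Pixel coordinates are 0-based.  A :class:`BoundingBox` ``(x, y, w, h)``
  covers the half-open pixel interval ``[x, x+w) x [y, y+h)`` — ``x`` is the
  left edge (column), ``y`` the top edge (row).
* Grayscale polarity is canonical DSA: vessels are *dark* on a *bright*
  background, so "deeper grayscale" always means a lower intensity value.
  Loaders must set :attr:`GrayImage.vessels_dark` accordingly (inverting on
  request); every grayscale comparison downstream assumes the canonical
  convention.
"""

from __future__ import annotations

import csv
import enum
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "GrayImage",
    "BoundingBox",
    "Label",
    "View",
    "Detection",
    "FramePair",
    "PatientRecord",
    "AnnotationRecord",
    "AnnotationError",
    "iou",
    "read_annotations",
    "write_annotations",
    "load_image",
    "save_image",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid records."""


class Label(str, enum.Enum):
    """Closed set of object classes the pipeline knows about."""

    ANEURYSM = "aneurysm"
    OVERLAP = "overlap"
    REGION = "region"


class View(str, enum.Enum):
    FRONTAL = "frontal"
    LATERAL = "lateral"


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity raster with an explicit polarity convention.

    Parameters
    ----------
    pixels
        2D array, either 8-bit integers in [0, 255] or floats in [0, 1].
    vessels_dark
        True (canonical) when lower values mean more radiocontrast agent,
        i.e. vessels appear dark on a bright background.
    """

    pixels: np.ndarray
    vessels_dark: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if np.issubdtype(px.dtype, np.integer):
            lo, hi = 0, 255
        else:
            lo, hi = 0.0, 1.0
        if px.size and (px.min() < lo or px.max() > hi):
            raise ValueError(f"intensities outside declared range [{lo}, {hi}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def is_float(self) -> bool:
        return not np.issubdtype(self.pixels.dtype, np.integer)

    def max_intensity(self) -> float:
        """Upper bound of the declared intensity range (255 or 1.0)."""
        return 1.0 if self.is_float else 255


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box parameterized as (x, y, w, h), half-open in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def area(self) -> float:
        return self.w * self.h

    def intersects(self, other: "BoundingBox") -> bool:
        return (
            self.x < other.x2
            and other.x < self.x2
            and self.y < other.y2
            and other.y < self.y2
        )

    def clipped(self, width: float, height: float) -> "BoundingBox":
        """Clip to the image rectangle [0, width) x [0, height)."""
        x1 = max(self.x, 0.0)
        y1 = max(self.y, 0.0)
        x2 = min(self.x2, float(width))
        y2 = min(self.y2, float(height))
        if x2 <= x1 or y2 <= y1:
            raise ValueError("box lies entirely outside the image")
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)

    def scaled(self, factor: float) -> "BoundingBox":
        """Grow width and height by ``factor`` about the same center."""
        cx, cy = self.centroid
        w, h = self.w * factor, self.h * factor
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)

    def pixel_slices(self) -> tuple[slice, slice]:
        """Integer (row, col) slices of the covered pixel lattice."""
        x1, y1 = int(math.floor(self.x)), int(math.floor(self.y))
        x2, y2 = int(math.ceil(self.x2)), int(math.ceil(self.y2))
        return slice(y1, y2), slice(x1, x2)


@dataclass(frozen=True)
class Detection:
    """A labeled box with a confidence score."""

    box: BoundingBox
    label: Label
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(self.label))


@dataclass
class FramePair:
    """Matched frontal/lateral frames at the same sequence index."""

    patient_id: str
    frame_index: int
    frontal: GrayImage
    lateral: GrayImage

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def view(self, which: View) -> GrayImage:
        return self.frontal if which is View.FRONTAL else self.lateral


@dataclass
class PatientRecord:
    """A patient's ordered biplane sequence with ground truth."""

    patient_id: str
    frames: list[FramePair]
    truth_diagnosis: bool
    #: truth_boxes[frame_index][view] -> list of (label, BoundingBox)
    truth_boxes: dict[int, dict[View, list[tuple[Label, BoundingBox]]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("PatientRecord requires at least one frame")
        n = len(self.frames)
        for idx in self.truth_boxes:
            if not 0 <= idx < n:
                raise ValueError(f"truth box frame index {idx} out of range [0, {n})")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes under the half-open convention.

    Symmetric, in [0, 1]; 0 for disjoint boxes, 1 for identical ones.
    """
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area() + b.area() - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Annotation I/O
#
# CSV schema: patient_id,frame_index,view,label,x,y,w,h,confidence
# (confidence left empty for ground-truth boxes).  JSON mirrors the schema as
# a list of objects with the same keys.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["patient_id", "frame_index", "view", "label", "x", "y", "w", "h", "confidence"]


@dataclass(frozen=True)
class AnnotationRecord:
    patient_id: str
    frame_index: int
    view: View
    label: Label
    box: BoundingBox
    confidence: float | None = None  # None for ground truth

    def to_detection(self) -> Detection:
        if self.confidence is None:
            raise ValueError("ground-truth record has no confidence")
        return Detection(self.box, self.label, self.confidence)


def _parse_row(row: dict[str, str], where: str) -> AnnotationRecord:
    try:
        view = View(row["view"])
    except ValueError as exc:
        raise AnnotationError(f"{where}: unknown view {row['view']!r}") from exc
    try:
        label = Label(row["label"])
    except ValueError as exc:
        raise AnnotationError(f"{where}: unknown label {row['label']!r}") from exc
    try:
        frame_index = int(row["frame_index"])
        x, y = float(row["x"]), float(row["y"])
        w, h = float(row["w"]), float(row["h"])
    except (ValueError, KeyError) as exc:
        raise AnnotationError(f"{where}: malformed numeric field ({exc})") from exc
    conf_raw = (row.get("confidence") or "").strip()
    confidence = float(conf_raw) if conf_raw else None
    if confidence is not None and not 0.0 <= confidence <= 1.0:
        raise AnnotationError(f"{where}: confidence {confidence} outside [0,1]")
    if w <= 0 or h <= 0:
        raise AnnotationError(f"{where}: non-positive box size w={w}, h={h}")
    if frame_index < 0:
        raise AnnotationError(f"{where}: negative frame_index {frame_index}")
    return AnnotationRecord(row["patient_id"], frame_index, view, label,
                            BoundingBox(x, y, w, h), confidence)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records from a CSV or JSON file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise AnnotationError(f"{path}: JSON annotations must be a list")
        return [
            _parse_row({k: "" if v is None else str(v) for k, v in row.items()},
                       f"{path} record {i}")
            for i, row in enumerate(rows)
        ]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise AnnotationError(f"{path}: empty file without header")
        if list(reader.fieldnames) != _CSV_HEADER:
            raise AnnotationError(
                f"{path}: unexpected header {reader.fieldnames}, want {_CSV_HEADER}"
            )
        out = []
        for i, row in enumerate(reader, start=2):
            if any(v is None for v in row.values()):
                raise AnnotationError(f"{path} line {i}: wrong number of fields")
            out.append(_parse_row(row, f"{path} line {i}"))
        return out


def _fmt(v: float) -> str:
    # >= 6 significant digits survive the round trip; %.9g is lossless enough
    # for pixel coordinates and confidences.
    return format(float(v), ".9g")


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write records as CSV or JSON (by extension); round-trips losslessly."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        rows = [
            {
                "patient_id": r.patient_id,
                "frame_index": r.frame_index,
                "view": r.view.value,
                "label": r.label.value,
                "x": r.box.x,
                "y": r.box.y,
                "w": r.box.w,
                "h": r.box.h,
                "confidence": r.confidence,
            }
            for r in records
        ]
        path.write_text(json.dumps(rows, indent=1))
        return
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(_CSV_HEADER)
    for r in records:
        writer.writerow(
            [
                r.patient_id,
                r.frame_index,
                r.view.value,
                r.label.value,
                _fmt(r.box.x),
                _fmt(r.box.y),
                _fmt(r.box.w),
                _fmt(r.box.h),
                "" if r.confidence is None else _fmt(r.confidence),
            ]
        )
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Image I/O (PNG, 8-bit single channel; RGB collapsed by channel mean)
# ---------------------------------------------------------------------------


def load_image(path: str | Path, vessels_dark: bool = True, invert: bool = False) -> GrayImage:
    """Load a PNG as an 8-bit :class:`GrayImage`.

    3-channel inputs are collapsed by the channel mean.  ``invert=True``
    flips intensities (255 - v) for sources with bright-vessel polarity.
    """
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    arr = np.round(arr).astype(np.uint8)
    if invert:
        arr = 255 - arr
    return GrayImage(arr, vessels_dark=vessels_dark)


def save_image(image: GrayImage, path: str | Path) -> None:
    from PIL import Image

    px = image.pixels
    if image.is_float:
        px = np.round(px * 255.0)
    Image.fromarray(px.astype(np.uint8), mode="L").save(path)
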