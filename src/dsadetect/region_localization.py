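"""Stage 1: locate the target arterial region and crop to the 288x288 interface.

A full 1024x1024 angiogram mostly shows tissue and unrelated vasculature;
the detection stage works on a fixed-size crop of the region of interest
(here the posterior communicating artery territory).  This module defines
the pluggable localizer contract, a classical reference localizer based on
vessel-pixel density, the crop-and-resize step, and the centroid-offset
quality metrics.

"Not found" is an explicit result, not an error: sequences exist where the
region cannot be located (e.g. the junction occluded by a huge aneurysm),
and downstream stages simply skip those frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize as _sk_resize

from .core_types import BoundingBox, GrayImage
from .rags import vessel_mask

__all__ = [
    "CROP_SIZE",
    "AffineMap",
    "RegionResult",
    "ReferenceLocalizer",
    "localize",
    "crop_and_resize",
    "regularized_offsets",
]

CROP_SIZE = 288


@dataclass(frozen=True)
class AffineMap:
    """Axis-aligned affine map from crop coordinates to full-frame coordinates."""

    scale_x: float
    scale_y: float
    offset_x: float
    offset_y: float

    def forward(self, x: float, y: float) -> tuple[float, float]:
        return self.offset_x + self.scale_x * x, self.offset_y + self.scale_y * y

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.offset_x) / self.scale_x, (y - self.offset_y) / self.scale_y

    def box_to_full(self, box: BoundingBox) -> BoundingBox:
        x1, y1 = self.forward(box.x, box.y)
        x2, y2 = self.forward(box.x2, box.y2)
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class RegionResult:
    """A located region: box in full-frame coordinates plus the 288x288 crop."""

    region_box: BoundingBox
    confidence: float
    crop: GrayImage
    transform: AffineMap

    def __post_init__(self) -> None:
        if self.crop.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}, got {self.crop.shape}")


#: A localizer proposes zero or more (box, confidence) candidates on a frame.
LocalizerFn = Callable[[GrayImage], list[tuple[BoundingBox, float]]]


def crop_and_resize(
    image: GrayImage, box: BoundingBox
) -> tuple[GrayImage, AffineMap]:
    """Crop ``box`` (clipped to bounds) and bilinearly resample to 288x288.

    Returns the crop and the affine map taking crop pixel coordinates back
    to full-frame coordinates; corner round trips are sub-half-pixel.
    Raises ``ValueError`` when the box lies fully outside the image.
    """
    h, w = image.shape
    clipped = box.clipped(w, h)  # raises if fully outside
    rs, cs = clipped.pixel_slices()
    sub = image.pixels[rs, cs]
    transform = AffineMap(
        scale_x=sub.shape[1] / CROP_SIZE,
        scale_y=sub.shape[0] / CROP_SIZE,
        offset_x=float(cs.start),
        offset_y=float(rs.start),
    )
    if sub.shape == (CROP_SIZE, CROP_SIZE):
        out = sub  # identity resample: keep pixels bit-exact
    else:
        resampled = _sk_resize(
            sub.astype(np.float64),
            (CROP_SIZE, CROP_SIZE),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        out = (
            np.clip(np.round(resampled), 0, 255).astype(sub.dtype)
            if not image.is_float
            else np.clip(resampled, 0.0, 1.0)
        )
    return GrayImage(out, vessels_dark=image.vessels_dark), transform


class ReferenceLocalizer:
    """Classical vessel-density localizer (stands in for a learned model).

    Scores a coarse sliding grid of square windows by the fraction of
    vessel-mask pixels they contain; the densest window wins, and the
    confidence is the window's density normalized by a saturation density
    (capped at 1).  Frames whose global vessel fraction falls below
    ``min_vessel_fraction`` yield no candidates.
    """

    def __init__(
        self,
        window: int = CROP_SIZE,
        stride: int = 32,
        min_vessel_fraction: float = 1e-4,
        saturation_density: float = 0.08,
    ) -> None:
        self.window = window
        self.stride = stride
        self.min_vessel_fraction = min_vessel_fraction
        self.saturation_density = saturation_density

    def __call__(self, image: GrayImage) -> list[tuple[BoundingBox, float]]:
        h, w = image.shape
        try:
            mask = vessel_mask(image)
        except ValueError:  # constant image: nothing to segment
            return []
        if mask.mean() < self.min_vessel_fraction:
            return []
        # integral image makes each window score O(1)
        ii = np.zeros((h + 1, w + 1), dtype=np.int64)
        ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
        win = min(self.window, h, w)
        ys = list(range(0, h - win + 1, self.stride)) or [0]
        xs = list(range(0, w - win + 1, self.stride)) or [0]
        best = None
        for y in ys:
            for x in xs:
                count = (
                    ii[y + win, x + win] - ii[y, x + win] - ii[y + win, x] + ii[y, x]
                )
                if best is None or count > best[0]:
                    best = (count, x, y)
        assert best is not None
        count, x, y = best
        if count == 0:
            return []
        # refine: recenter the window on the bounding box of the vessel
        # mask within a 1.5x neighborhood of the coarse winner, which
        # corrects the drift of a pure density argmax when the vasculature
        # sits asymmetrically inside the window
        pad = win // 4
        ny0, ny1 = max(0, y - pad), min(h, y + win + pad)
        nx0, nx1 = max(0, x - pad), min(w, x + win + pad)
        local = mask[ny0:ny1, nx0:nx1]
        rows = np.flatnonzero(local.any(axis=1))
        cols = np.flatnonzero(local.any(axis=0))
        if rows.size and cols.size:
            cy = ny0 + (rows[0] + rows[-1] + 1) / 2.0
            cx = nx0 + (cols[0] + cols[-1] + 1) / 2.0
            x = int(np.clip(round(cx - win / 2), 0, w - win))
            y = int(np.clip(round(cy - win / 2), 0, h - win))
            count = (
                ii[y + win, x + win] - ii[y, x + win] - ii[y + win, x] + ii[y, x]
            )
        density = count / (win * win)
        confidence = min(1.0, density / self.saturation_density)
        return [(BoundingBox(float(x), float(y), float(win), float(win)), confidence)]


def localize(
    image: GrayImage, localizer: LocalizerFn | None = None
) -> RegionResult | None:
    """Locate the target region on a full frame; ``None`` means not found.

    At most one region is returned per frame — the highest-confidence
    candidate wins.  The crop is resized to the fixed 288x288 detection
    interface with the recorded inverse transform.
    """
    if localizer is None:
        localizer = ReferenceLocalizer()
    candidates = localizer(image)
    if not candidates:
        return None
    box, confidence = max(candidates, key=lambda bc: bc[1])
    crop, transform = crop_and_resize(image, box)
    return RegionResult(
        region_box=box, confidence=confidence, crop=crop, transform=transform
    )


def regularized_offsets(
    annotation: BoundingBox, prediction: BoundingBox
) -> tuple[float, float]:
    """Centroid offsets normalized by the manual annotation's size.

    ``off_x = |x_ann - x_pred| / W`` and ``off_y = |y_ann - y_pred| / H``,
    where centroids are box centers and W, H are the annotation's width and
    height.  Translation-invariant and scale-covariant: scaling both boxes
    by the same factor leaves the offsets unchanged.
    """
    if annotation.w <= 0 or annotation.h <= 0:
        raise ValueError("annotation box must have positive width and height")
    ax, ay = annotation.centroid
    px, py = prediction.centroid
    return abs(ax - px) / annotation.w, abs(ay - py) / annotation.h
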