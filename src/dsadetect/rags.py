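"""Regional Average Grayscale Suppression (RAGS) of false-positive aneurysms.

In DSA the gray value of a pixel reflects the amount of radiocontrast agent
along the ray behind it: an apparent mass created by two vessels crossing in
projection contains *more* blood than its neighborhood and therefore reads
darker, while a small aneurysm sac reads lighter than its parent vessel.
RAGS turns this into a decision rule.  For every detected aneurysm whose
confidence falls below a threshold ``c``:

1. extract a rough vessel mask of the region crop with Otsu's method and
   keep original intensities only on the mask;
2. form an enlargement box by doubling the detection's width and height
   about the same center (clipped to the image);
3. average the masked gray values inside the detection box
   (``AG_aneurysm = G_an / P_an``) and over the surrounding ring
   (``AG_surrounding = (G_enl - G_an) / (P_enl - P_an)``);
4. if ``AG_aneurysm < AG_surrounding`` (strictly darker than its surround),
   the object is declared a vessel overlap and suppressed; otherwise the
   aneurysm label is retained.

Averages are taken over vessel-mask pixels only: including the masked-out
background (zeroed by the logical AND) would drag sparse boxes toward
darkness and bias the comparison.  Ties retain the aneurysm label,
consistent with the high-sensitivity design goal.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core_types import BoundingBox, Detection, GrayImage, Label

__all__ = [
    "RagsConfig",
    "RagsRegions",
    "RagsDecision",
    "SuppressionAction",
    "DegenerateRegionError",
    "otsu_threshold",
    "vessel_mask",
    "compute_regions",
    "rags_decide",
    "apply_rags",
]

log = logging.getLogger(__name__)


class SuppressionAction(str, enum.Enum):
    RELABEL_OVERLAP = "relabel_overlap"
    DROP = "drop"


class RagsDecision(str, enum.Enum):
    RETAIN = "retain"
    SUPPRESS = "suppress"


class DegenerateRegionError(ValueError):
    """No vessel pixels in the box, or an empty surrounding ring."""


@dataclass(frozen=True)
class RagsConfig:
    """Tunables of the suppression rule.

    ``c`` gates which detections are tested (confidence strictly below
    ``c``); the default 0.99 tests nearly everything, chosen to balance the
    patient disease-confidence distribution.  ``enlargement_factor`` 2.0
    doubles width and height about the same center.
    """

    c: float = 0.99
    enlargement_factor: float = 2.0
    action: SuppressionAction = SuppressionAction.RELABEL_OVERLAP
    min_ring_pixels: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must be in [0,1], got {self.c}")
        if self.enlargement_factor <= 1.0:
            raise ValueError("enlargement_factor must be > 1")


@dataclass(frozen=True)
class RagsRegions:
    """Grayscale sums, pixel counts and averages of the two ROIs."""

    aneurysm_roi: BoundingBox
    enlargement_roi: BoundingBox
    g_aneurysm: float
    p_aneurysm: int
    g_enlargement: float
    p_enlargement: int

    @property
    def ag_aneurysm(self) -> float:
        if self.p_aneurysm == 0:
            raise DegenerateRegionError("no vessel pixels inside the aneurysm ROI")
        return self.g_aneurysm / self.p_aneurysm

    @property
    def ag_surrounding(self) -> float:
        ring = self.p_enlargement - self.p_aneurysm
        if ring <= 0:
            raise DegenerateRegionError("empty surrounding ring")
        return (self.g_enlargement - self.g_aneurysm) / ring

    @property
    def degenerate(self) -> bool:
        return self.p_aneurysm == 0 or self.p_enlargement - self.p_aneurysm <= 0


# ---------------------------------------------------------------------------
# Otsu vessel extraction
# ---------------------------------------------------------------------------


def _histogram_256(image: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram and bin values; float inputs binned to 256 levels."""
    px = image.pixels
    if image.is_float:
        levels = np.minimum((px * 256.0).astype(np.int64), 255)
        values = (np.arange(256) + 0.5) / 256.0
    else:
        levels = px.astype(np.int64)
        values = np.arange(256, dtype=np.float64)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    return hist, values


def otsu_threshold(image: GrayImage) -> float:
    """Intensity threshold maximizing between-class variance (256 bins).

    The returned threshold t splits pixels into classes ``value <= t`` and
    ``value > t``; ties in the variance scan break toward the lower
    threshold.  Raises ``ValueError`` on a constant image (no separation).
    """
    hist, values = _histogram_256(image)
    nz = np.flatnonzero(hist)
    if nz.size < 2:
        raise ValueError("Otsu requires at least two distinct intensity levels")
    total = hist.sum()
    w0 = np.cumsum(hist)  # pixels with level <= t
    mu = np.cumsum(hist * values)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = total - w0
        between = np.where(
            (w0 > 0) & (w1 > 0),
            (mu_total * w0 - mu * total) ** 2 / (w0 * w1),
            -np.inf,
        )
    best = int(np.argmax(between))  # argmax takes the first (lowest) maximizer
    return float(values[best])


def vessel_mask(image: GrayImage) -> np.ndarray:
    """Binary vessel mask: pixels on the darker side of the Otsu threshold.

    Requires the canonical polarity (vessels dark on bright background); the
    masked image is the original intensities *on* the mask — background is
    excluded, never averaged in.
    """
    if not image.vessels_dark:
        raise ValueError(
            "vessel_mask requires canonical polarity (vessels dark); "
            "invert the image on load"
        )
    t = otsu_threshold(image)
    return image.pixels <= t


# ---------------------------------------------------------------------------
# regional averages and the decision rule
# ---------------------------------------------------------------------------


def _masked_sum(image: GrayImage, mask: np.ndarray, box: BoundingBox) -> tuple[float, int]:
    rs, cs = box.pixel_slices()
    sub = image.pixels[rs, cs]
    m = mask[rs, cs]
    return float(sub[m].sum()), int(m.sum())


def compute_regions(
    image: GrayImage,
    mask: np.ndarray,
    prediction: Detection,
    config: RagsConfig = RagsConfig(),
) -> RagsRegions:
    """Grayscale sums/counts over the detection box and its enlargement.

    The enlargement box shares the detection's center with width and height
    multiplied by ``config.enlargement_factor``, clipped to image bounds.
    Sums run over vessel-mask pixels only.
    """
    h_img, w_img = image.shape
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    box = prediction.box.clipped(w_img, h_img)
    enl = prediction.box.scaled(config.enlargement_factor).clipped(w_img, h_img)
    g_an, p_an = _masked_sum(image, mask, box)
    g_en, p_en = _masked_sum(image, mask, enl)
    return RagsRegions(
        aneurysm_roi=box,
        enlargement_roi=enl,
        g_aneurysm=g_an,
        p_aneurysm=p_an,
        g_enlargement=g_en,
        p_enlargement=p_en,
    )


def rags_decide(regions: RagsRegions) -> RagsDecision:
    """Suppress iff the object is strictly darker than its surround.

    ``AG_aneurysm < AG_surrounding`` means the object holds more contrast
    agent than the neighboring vessel — the signature of an overlap.
    Equality retains.  Degenerate regions retain with a warning: with no
    evidence either way the high-sensitivity goal keeps the aneurysm.
    """
    if regions.degenerate:
        warnings.warn(
            "degenerate RAGS region (no vessel pixels or empty ring); retaining",
            stacklevel=2,
        )
        return RagsDecision.RETAIN
    if regions.ag_aneurysm < regions.ag_surrounding:
        return RagsDecision.SUPPRESS
    return RagsDecision.RETAIN


def apply_rags(
    detections: list[Detection],
    image: GrayImage,
    config: RagsConfig = RagsConfig(),
    mask: np.ndarray | None = None,
) -> list[Detection]:
    """Run the suppression rule over a detection list.

    Only aneurysm-labeled detections with confidence strictly below
    ``config.c`` are tested; confident detections and overlap/region labels
    pass through untouched.  Suppression either relabels the detection as an
    overlap (default, keeping the box) or drops it.
    """
    tested = [
        d
        for d in detections
        if d.label is Label.ANEURYSM and d.confidence < config.c
    ]
    if not tested:
        return list(detections)
    if mask is None:
        mask = vessel_mask(image)
    out: list[Detection] = []
    for det in detections:
        if not (det.label is Label.ANEURYSM and det.confidence < config.c):
            out.append(det)
            continue
        try:
            regions = compute_regions(image, mask, det, config)
        except ValueError:
            log.warning("RAGS box outside image for %s; retained", det)
            out.append(det)
            continue
        if rags_decide(regions) is RagsDecision.SUPPRESS:
            if config.action is SuppressionAction.RELABEL_OVERLAP:
                out.append(replace(det, label=Label.OVERLAP))
            # DROP: omit entirely
        else:
            out.append(det)
    return out
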