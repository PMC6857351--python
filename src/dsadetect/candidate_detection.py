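"""Stage 2 front half: dual-view input pairing and candidate detection.

Frontal and lateral angiograms are acquired simultaneously and share the
craniocaudal axis, so a structure at image row z in one view must appear at
the same row in the other *if it is real 3D anatomy*.  A vessel overlap is a
projection artifact: it exists at that row in one view only.  The dual-input
design exploits this: the detector sees the target crop together with the
same-index crop from the orthogonal view and can discount bulges with no
orthogonal counterpart.

The detector itself is pluggable (any callable from :class:`DualInput` to a
detection list).  The built-in :class:`ReferenceDetector` is a classical
stand-in in the spirit of pre-learning vascular image analysis: Otsu vessel
mask, medial-axis radius profile, and local radius maxima that exceed the
surrounding caliber, scored by a logistic function of the radius excess with
a dual-view correspondence bonus/penalty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .core_types import BoundingBox, Detection, FramePair, GrayImage, Label, View
from .rags import vessel_mask

__all__ = [
    "DualInput",
    "DetectorFn",
    "make_dual_inputs",
    "detect_candidates",
    "ReferenceDetector",
    "retain_confident",
    "RETENTION_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Detections are kept only when strictly more confident than this.
RETENTION_THRESHOLD = 0.6


@dataclass(frozen=True)
class DualInput:
    """A target crop paired with the same-index crop from the other view."""

    target: GrayImage
    corresponding: GrayImage | None
    target_view: View

    def __post_init__(self) -> None:
        if (
            self.corresponding is not None
            and self.target.shape != self.corresponding.shape
        ):
            raise ValueError("target and corresponding crops must share a size")

    def stacked(self) -> np.ndarray:
        """Channel-stacked representation; the target is always channel 0."""
        if self.corresponding is None:
            return self.target.pixels[None, ...]
        return np.stack([self.target.pixels, self.corresponding.pixels])


DetectorFn = Callable[[DualInput], list[Detection]]


_UNSET = object()


def make_dual_inputs(
    pair: FramePair,
    frontal: GrayImage | None | object = _UNSET,
    lateral: GrayImage | None | object = _UNSET,
) -> list[DualInput]:
    """Build the two dual inputs of a frame pair (each view once as target).

    ``frontal``/``lateral`` override the pair's images (e.g. region crops
    produced by the localization stage); passing ``None`` explicitly marks a
    view as missing (localization failed there) — the frame then contributes
    only the available single view, with a log note.
    """
    fr = pair.frontal if frontal is _UNSET else frontal
    la = pair.lateral if lateral is _UNSET else lateral
    out: list[DualInput] = []
    if fr is not None:
        out.append(DualInput(target=fr, corresponding=la, target_view=View.FRONTAL))
    if la is not None:
        out.append(DualInput(target=la, corresponding=fr, target_view=View.LATERAL))
    if len(out) < 2:
        log.warning(
            "frame %s/%d: only %d view(s) available",
            pair.patient_id,
            pair.frame_index,
            len(out),
        )
    return out


def detect_candidates(dual: DualInput, detector: DetectorFn) -> list[Detection]:
    """Run a detector on a dual input; returns the raw, unfiltered candidates.

    Detections are reported in the coordinates of the *target* crop.
    """
    return list(detector(dual))


def retain_confident(
    candidates: list[Detection], threshold: float = RETENTION_THRESHOLD
) -> list[Detection]:
    """Keep detections whose confidence is strictly above the threshold.

    Order-preserving, idempotent, never lengthens the list.
    """
    return [d for d in candidates if d.confidence > threshold]


# ---------------------------------------------------------------------------
# reference detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Peak:
    row: float
    col: float
    radius: float
    ratio: float  # radius / surrounding median radius


class ReferenceDetector:
    """Classical radius-excess detector with dual-view correspondence.

    A candidate is a medial-axis point whose lumen radius exceeds the median
    radius of the skeleton in a surrounding annulus by ``min_ratio``.  The
    base pseudo-confidence is ``sigmoid(slope * (ratio - mid))``; in dual
    mode a matching peak at the same image row in the corresponding view
    raises the confidence (``conf + bonus*(1-conf)``) and a missing match
    multiplies it by ``penalty``.  Emits aneurysm candidates only — telling
    apparent overlaps from true dilations is the suppression stage's job.
    """

    def __init__(
        self,
        *,
        dual_view: bool = True,
        min_ratio: float = 1.3,
        match_ratio: float = 1.2,
        min_radius_px: float = 3.0,
        logistic_mid: float = 1.45,
        logistic_slope: float = 5.0,
        base_scale: float = 0.95,
        match_row_tol: float = 9.0,
        match_radius_rtol: float = 0.35,
        match_bonus: float = 0.5,
        unmatched_penalty: float = 0.65,
        peak_separation_px: float = 30.0,
        annulus_px: tuple[float, float] = (25.0, 70.0),
        box_scale: float = 2.8,
    ) -> None:
        self.dual_view = dual_view
        self.min_ratio = min_ratio
        self.match_ratio = match_ratio
        self.min_radius_px = min_radius_px
        self.logistic_mid = logistic_mid
        self.logistic_slope = logistic_slope
        self.base_scale = base_scale
        self.match_row_tol = match_row_tol
        self.match_radius_rtol = match_radius_rtol
        self.match_bonus = match_bonus
        self.unmatched_penalty = unmatched_penalty
        self.peak_separation_px = peak_separation_px
        self.annulus_px = annulus_px
        self.box_scale = box_scale

    # -- radius profile ----------------------------------------------------

    def _peaks(self, image: GrayImage, min_ratio: float) -> list[_Peak]:
        try:
            mask = vessel_mask(image)
        except ValueError:
            return []  # blank / constant frame
        if not mask.any():
            return []
        dist = distance_transform_edt(mask)
        skel = skeletonize(mask)
        coords = np.argwhere(skel)
        if coords.shape[0] < 10:
            return []
        radii = dist[coords[:, 0], coords[:, 1]]
        d = np.linalg.norm(
            coords[:, None, :].astype(float) - coords[None, :, :].astype(float),
            axis=2,
        )
        lo, hi = self.annulus_px
        peaks: list[_Peak] = []
        local = d <= self.peak_separation_px / 2
        annulus = (d >= lo) & (d <= hi)
        for i in range(coords.shape[0]):
            r = radii[i]
            if r < self.min_radius_px:
                continue
            if r < radii[local[i]].max():
                continue
            ring_r = radii[annulus[i]]
            if ring_r.size < 5:
                continue
            med = float(np.median(ring_r))
            if med <= 0:
                continue
            ratio = float(r / med)
            if ratio >= min_ratio:
                peaks.append(
                    _Peak(row=float(coords[i, 0]), col=float(coords[i, 1]),
                          radius=float(r), ratio=ratio)
                )
        # greedy non-max suppression by ratio
        peaks.sort(key=lambda p: p.ratio, reverse=True)
        kept: list[_Peak] = []
        for p in peaks:
            if all(
                math.hypot(p.row - q.row, p.col - q.col) > self.peak_separation_px
                for q in kept
            ):
                kept.append(p)
        return kept

    def base_confidence(self, ratio: float) -> float:
        """Logistic in the radius excess, capped at ``base_scale``.

        The cap keeps classical pseudo-confidences below the suppression
        gate c, so every candidate this detector emits remains eligible for
        the grayscale check — a hand-crafted radius ratio never carries the
        near-certainty a strong learned detector can claim.
        """
        s = 1.0 / (1.0 + math.exp(-self.logistic_slope * (ratio - self.logistic_mid)))
        return self.base_scale * s

    # -- detection ---------------------------------------------------------

    def __call__(self, dual: DualInput) -> list[Detection]:
        peaks = self._peaks(dual.target, self.min_ratio)
        if not peaks:
            return []
        corr_peaks: list[_Peak] = []
        use_dual = self.dual_view and dual.corresponding is not None
        if use_dual:
            corr_peaks = self._peaks(dual.corresponding, self.match_ratio)
        h, w = dual.target.shape
        out: list[Detection] = []
        for p in peaks:
            conf = self.base_confidence(p.ratio)
            if use_dual:
                # a real 3D sac is (roughly) a sphere: it appears at the same
                # craniocaudal row with a similar apparent radius in both
                # views, while a projection crossing generally does not
                matched = any(
                    abs(p.row - q.row) <= self.match_row_tol
                    and abs(p.radius - q.radius)
                    <= self.match_radius_rtol * max(p.radius, q.radius)
                    for q in corr_peaks
                )
                if matched:
                    conf = conf + self.match_bonus * (1.0 - conf)
                else:
                    conf = conf * self.unmatched_penalty
            half = self.box_scale * p.radius / 2.0
            x1 = max(0.0, p.col - half)
            y1 = max(0.0, p.row - half)
            x2 = min(float(w), p.col + half)
            y2 = min(float(h), p.row + half)
            if x2 - x1 < 1 or y2 - y1 < 1:
                continue
            out.append(
                Detection(
                    BoundingBox(x1, y1, x2 - x1, y2 - y1),
                    Label.ANEURYSM,
                    min(1.0, conf),
                )
            )
        return out
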