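"""Seeded simulator of paired frontal/lateral DSA-like angiograms.

The simulator builds a small 3D vessel tree (smooth tubes in the unit cube),
voxelizes it, and projects the lumen chord length through every pixel's ray:
the frontal view integrates out the depth axis (y), the lateral view the
left-right axis (x), and both share the craniocaudal axis (z) as the image
row.  Pixel intensity follows a linear attenuation model,

    I(p) = clip(255 - gain * k * L(p)) + noise,

where ``L(p)`` is the density-weighted chord length of contrast-filled lumen
along the ray through ``p``.  Two consequences matter for the detection
pipeline and are guaranteed by construction:

* a projection-only *crossing* of two distinct vessels sums both chords, so
  overlap pixels are strictly darker than single-vessel pixels of the same
  caliber (noise-free);
* an aneurysm dome is a genuine 3D dilation (dome radius > lumen radius), so
  it bulges in *both* views, but its interior carries a reduced contrast
  density (stagnant flow in the sac), so small domes read *lighter* than the
  surrounding vessel — the grayscale signature the suppression rule exploits.

Full frames embed the vascular region in a bright 1024x1024 canvas at a
recorded window, giving the localization stage its ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .core_types import (
    BoundingBox,
    FramePair,
    GrayImage,
    Label,
    PatientRecord,
    View,
)

__all__ = [
    "Curve",
    "Aneurysm",
    "ViewTruth",
    "SyntheticScene",
    "GenerationError",
    "generate_scene",
    "curve_chord_map",
    "chord_maps",
    "render_views",
    "render_full_views",
    "render_sequence",
    "default_washin",
    "write_patient_dir",
]

BACKGROUND = 255.0


class GenerationError(RuntimeError):
    """Raised when the retry budget for a scene constraint is exhausted."""


@dataclass(frozen=True)
class Curve:
    """A vessel centerline: dense 3D polyline with per-point lumen radius."""

    points: np.ndarray  # (n, 3) in the unit cube, axes (x, y, z)
    radii: np.ndarray  # (n,)


@dataclass(frozen=True)
class Aneurysm:
    """A saccular dome budding sideways off a centerline point.

    The spherical sac's center sits ``offset_frac * dome_radius`` away from
    the attachment point in the horizontal direction ``offset_dir`` (unit
    x-y vector) and is joined to the lumen by a thin contrast-filled neck
    tube, so the sac projects *beside* its parent vessel in both views — as
    saccular aneurysms do in biplane DSA.  ``density`` is the contrast-agent
    density in the sac relative to flowing lumen (1.0); values below 1 make
    the dome read lighter than its parent vessel, reflecting slow, stagnant
    flow in the sac.
    """

    curve_id: int
    arc_pos: float  # parameter in [0, 1] along the centerline
    dome_radius: float  # unit-cube units; > local lumen radius
    density: float = 0.4
    offset_dir: tuple[float, float] = (0.7071067811865476, 0.7071067811865476)
    offset_frac: float = 2.4
    neck_radius_frac: float = 0.5  # of the local lumen radius


@dataclass
class ViewTruth:
    """Per-view ground truth, in region-crop pixel coordinates."""

    region_box: BoundingBox  # in full-frame coordinates
    aneurysm_boxes: list[BoundingBox]
    overlap_boxes: list[BoundingBox]
    vessel_mask: np.ndarray  # bool, region_size x region_size

    def labeled_boxes(self) -> list[tuple[Label, BoundingBox]]:
        out: list[tuple[Label, BoundingBox]] = [(Label.REGION, self.region_box)]
        out += [(Label.ANEURYSM, b) for b in self.aneurysm_boxes]
        out += [(Label.OVERLAP, b) for b in self.overlap_boxes]
        return out


@dataclass
class SyntheticScene:
    """Vessel tree plus rendering parameters; fully determined by its fields."""

    curves: list[Curve]
    aneurysms: list[Aneurysm]
    region_size: int = 288
    full_size: int = 1024
    gain_k: float = 2000.0  # gray levels per unit chord length
    noise_sd: float = 2.0  # Gaussian pixel noise, 8-bit gray levels
    seed: int = 0
    #: top-left corner of the embedded region window per view (full frame)
    region_offsets: dict[View, tuple[int, int]] = field(
        default_factory=lambda: {View.FRONTAL: (368, 368), View.LATERAL: (368, 368)}
    )

    def __post_init__(self) -> None:
        for an in self.aneurysms:
            r_local = _local_radius(self.curves[an.curve_id], an.arc_pos)
            if an.dome_radius <= r_local:
                raise ValueError(
                    f"aneurysm dome radius {an.dome_radius:.4f} must exceed the "
                    f"local lumen radius {r_local:.4f} (it is a dilation)"
                )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _arc_index(curve: Curve, t: float) -> int:
    return int(round(t * (len(curve.points) - 1)))


def _local_radius(curve: Curve, t: float) -> float:
    return float(curve.radii[_arc_index(curve, t)])


def _dome_center(curve: Curve, an: "Aneurysm | None" = None, t: float | None = None) -> np.ndarray:
    if an is not None:
        p = curve.points[_arc_index(curve, an.arc_pos)].copy()
        off = an.offset_frac * an.dome_radius
        p[0] += off * an.offset_dir[0]
        p[1] += off * an.offset_dir[1]
        return p
    assert t is not None
    return curve.points[_arc_index(curve, t)]


def _voxelize_spheres(
    occ: np.ndarray, centers: np.ndarray, radii: np.ndarray
) -> None:
    """Union-of-spheres rasterization into a boolean (G,G,G) grid, in place.

    Centerline samples are spaced well below the lumen radius, so the union
    of spheres is an accurate tube.
    """
    G = occ.shape[0]
    ax = (np.arange(G) + 0.5) / G
    for c, r in zip(centers, radii):
        lo = np.clip(np.floor((c - r) * G).astype(int), 0, G)
        hi = np.clip(np.ceil((c + r) * G).astype(int) + 1, 0, G)
        if np.any(lo >= hi):
            continue
        dx = ax[lo[0]:hi[0]] - c[0]
        dy = ax[lo[1]:hi[1]] - c[1]
        dz = ax[lo[2]:hi[2]] - c[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r


def _occupancy(curve: Curve, G: int) -> np.ndarray:
    occ = np.zeros((G, G, G), dtype=bool)
    _voxelize_spheres(occ, curve.points, curve.radii)
    return occ


def _project(occ_or_density: np.ndarray, view: View) -> np.ndarray:
    """Sum a voxel grid along the view's ray axis -> image [row=z, col]."""
    if view is View.FRONTAL:  # integrate out depth y; columns are x
        return occ_or_density.sum(axis=1, dtype=np.float64).T
    return occ_or_density.sum(axis=0, dtype=np.float64).T  # columns are y


def curve_chord_map(curve: Curve, G: int, view: View) -> np.ndarray:
    """Chord length (unit-cube units) of one tube along each pixel ray."""
    return _project(_occupancy(curve, G), view) / G


def chord_maps(scene: SyntheticScene) -> dict[View, np.ndarray]:
    """Density-weighted total chord maps for both views (cached on the scene).

    Dome voxels outside the parent lumen contribute with the dome's reduced
    density; all lumen voxels contribute 1.
    """
    cached = getattr(scene, "_chord_cache", None)
    if cached is not None:
        return cached
    G = scene.region_size
    maps = {v: np.zeros((G, G), dtype=np.float64) for v in View}
    union = np.zeros((G, G, G), dtype=bool)
    occs = []
    for curve in scene.curves:
        occ = _occupancy(curve, G)
        occs.append(occ)
        union |= occ
        for v in View:
            maps[v] += _project(occ, v) / G
    for an in scene.aneurysms:
        curve = scene.curves[an.curve_id]
        c = _dome_center(curve, an)
        anchor = curve.points[_arc_index(curve, an.arc_pos)]
        # neck: thin flowing-contrast tube from the lumen to the sac center
        neck_r = an.neck_radius_frac * _local_radius(curve, an.arc_pos)
        n_neck = max(int(np.linalg.norm(c - anchor) / (neck_r / 2)) + 1, 2)
        neck_pts = anchor + np.linspace(0, 1, n_neck)[:, None] * (c - anchor)
        neck = np.zeros((G, G, G), dtype=bool)
        _voxelize_spheres(neck, neck_pts, np.full(n_neck, neck_r))
        dome = np.zeros((G, G, G), dtype=bool)
        _voxelize_spheres(dome, c[None, :], np.array([an.dome_radius]))
        neck_only = neck & ~occs[an.curve_id] & ~dome
        dome_only = dome & ~occs[an.curve_id]
        for v in View:
            maps[v] += _project(neck_only, v) / G
            maps[v] += an.density * _project(dome_only, v) / G
    object.__setattr__(scene, "_chord_cache", maps)
    return maps


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _projected_point(p: np.ndarray, view: View, G: int) -> tuple[float, float]:
    """(col, row) pixel coordinates of a unit-cube point in a view."""
    col = (p[0] if view is View.FRONTAL else p[1]) * G
    return col, p[2] * G


def _find_crossings(
    scene: SyntheticScene, view: View
) -> list[tuple[float, float, float]]:
    """Projection-space crossings of distinct centerlines.

    Returns (col, row, size) in region pixels.  A crossing is a point where
    two centerlines come within their summed radii *in projection* while
    staying clearly apart in 3D — an apparent structure only.
    """
    G = scene.region_size
    out: list[tuple[float, float, float]] = []
    axes_2d = (0, 2) if view is View.FRONTAL else (1, 2)
    for a in range(len(scene.curves)):
        for b in range(a + 1, len(scene.curves)):
            ca, cb = scene.curves[a], scene.curves[b]
            pa2 = ca.points[:, axes_2d]
            pb2 = cb.points[:, axes_2d]
            d2d = np.linalg.norm(pa2[:, None, :] - pb2[None, :, :], axis=2)
            d3d = np.linalg.norm(
                ca.points[:, None, :] - cb.points[None, :, :], axis=2
            )
            rsum = ca.radii[:, None] + cb.radii[None, :]
            cand = (d2d < 0.8 * rsum) & (d3d > 1.5 * rsum)
            idx = np.argwhere(cand)
            if idx.size == 0:
                continue
            mids = 0.5 * (pa2[idx[:, 0]] + pb2[idx[:, 1]])
            sizes = rsum[idx[:, 0], idx[:, 1]]
            order = np.argsort(d2d[idx[:, 0], idx[:, 1]])
            taken: list[np.ndarray] = []
            for k in order:
                m = mids[k]
                if any(np.linalg.norm(m - t) < 0.08 for t in taken):
                    continue
                taken.append(m)
                out.append((m[0] * G, m[1] * G, sizes[k] * G))
    return out


def _box_around(col: float, row: float, half: float, G: int) -> BoundingBox:
    x1 = max(0.0, col - half)
    y1 = max(0.0, row - half)
    x2 = min(float(G), col + half)
    y2 = min(float(G), row + half)
    return BoundingBox(x1, y1, max(x2 - x1, 1.0), max(y2 - y1, 1.0))


def scene_truth(scene: SyntheticScene) -> dict[View, ViewTruth]:
    """Per-view ground truth: region window, aneurysm and overlap boxes."""
    G = scene.region_size
    maps = chord_maps(scene)
    # Truth vessel extent at full-width-half-maximum of a typical lumen:
    # a pixel counts as vessel when its chord exceeds one mean lumen radius
    # (half the diametral chord), excluding the faint partial-volume rim.
    if scene.curves:
        fwhm_chord = float(np.mean(np.concatenate([c.radii for c in scene.curves])))
    else:
        fwhm_chord = 0.0
    truths: dict[View, ViewTruth] = {}
    for v in View:
        an_boxes = []
        for an in scene.aneurysms:
            c = _dome_center(scene.curves[an.curve_id], an)
            col, row = _projected_point(c, v, G)
            an_boxes.append(_box_around(col, row, 1.3 * an.dome_radius * G, G))
        ov_boxes = [
            _box_around(col, row, 1.25 * size, G)
            for col, row, size in _find_crossings(scene, v)
        ]
        ox, oy = scene.region_offsets[v]
        truths[v] = ViewTruth(
            region_box=BoundingBox(float(ox), float(oy), float(G), float(G)),
            aneurysm_boxes=an_boxes,
            overlap_boxes=ov_boxes,
            vessel_mask=maps[v] > fwhm_chord,
        )
    return truths


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _random_curve(rng: np.random.Generator, n_samples: int = 400) -> Curve:
    """A smooth tube running roughly craniocaudally across the region."""
    t = np.linspace(0.0, 1.0, n_samples)
    z = 0.12 + 0.76 * t
    x0, x1 = rng.uniform(0.18, 0.82, size=2)
    y0, y1 = rng.uniform(0.18, 0.82, size=2)
    ax = rng.uniform(0.03, 0.10)
    ay = rng.uniform(0.02, 0.06)  # shallow depth wiggle keeps rays oblique
    phx, phy = rng.uniform(0, 2 * math.pi, size=2)
    fx, fy = rng.uniform(0.8, 1.5, size=2)
    x = x0 + (x1 - x0) * t + ax * np.sin(2 * math.pi * fx * t + phx)
    y = y0 + (y1 - y0) * t + ay * np.sin(2 * math.pi * fy * t + phy)
    x = np.clip(x, 0.08, 0.92)
    y = np.clip(y, 0.08, 0.92)
    base_r = rng.uniform(0.018, 0.028)
    radii = base_r * (1.0 - 0.15 * t)  # mild distal taper
    return Curve(points=np.column_stack([x, y, z]), radii=radii)


def generate_scene(
    n_vessels: int,
    n_aneurysms: int,
    seed: int,
    *,
    region_size: int = 288,
    full_size: int = 1024,
    noise_sd: float = 2.0,
    dome_ratio_range: tuple[float, float] = (2.0, 2.4),
    dome_density: float = 0.45,
    max_retries: int = 60,
) -> SyntheticScene:
    """Generate a reproducible scene; identical seed gives an identical scene.

    When ``n_vessels >= 2`` the generator retries until at least one pair of
    curves crosses in at least one projection (bounded retries), so negative
    cohorts reliably contain the overlap structures that mimic aneurysms.
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    if n_aneurysms < 0:
        raise ValueError("n_aneurysms must be >= 0")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        curves = [_random_curve(rng) for _ in range(n_vessels)]
        margin = region_size // 4
        offsets = {
            v: tuple(
                int(x)
                for x in rng.integers(
                    margin, full_size - region_size - margin, size=2
                )
            )
            for v in View
        }
        scene = SyntheticScene(
            curves=curves,
            aneurysms=[],
            region_size=region_size,
            full_size=full_size,
            noise_sd=noise_sd,
            seed=seed,
            region_offsets=offsets,  # type: ignore[arg-type]
        )
        crossings = {v: _find_crossings(scene, v) for v in View}
        if n_vessels >= 2 and not any(crossings.values()):
            continue
        aneurysms = _place_aneurysms(
            rng, curves, crossings, n_aneurysms, dome_ratio_range,
            dome_density, region_size,
        )
        if aneurysms is None:
            continue
        scene.aneurysms = aneurysms
        return scene
    raise GenerationError(
        f"could not satisfy scene constraints in {max_retries} attempts (seed={seed})"
    )


def _place_aneurysms(
    rng: np.random.Generator,
    curves: list[Curve],
    crossings: dict[View, list[tuple[float, float, float]]],
    n_aneurysms: int,
    ratio_range: tuple[float, float],
    density: float,
    G: int,
) -> list[Aneurysm] | None:
    """Place domes on centerlines, away from crossings and from each other."""
    placed: list[Aneurysm] = []
    centers: list[np.ndarray] = []
    for _ in range(n_aneurysms):
        ok = None
        for _try in range(40):
            cid = int(rng.integers(0, len(curves)))
            t = float(rng.uniform(0.25, 0.75))
            r_local = _local_radius(curves[cid], t)
            ratio = float(rng.uniform(*ratio_range))
            dome_r = ratio * r_local
            # bud direction with substantial x and y components, so the sac
            # projects clearly beside the vessel in both views
            phi = float(rng.uniform(math.radians(35), math.radians(55)))
            sx, sy = rng.choice([-1.0, 1.0], size=2)
            cand = Aneurysm(
                cid, t, dome_r, density,
                offset_dir=(sx * math.cos(phi), sy * math.sin(phi)),
            )
            c = _dome_center(curves[cid], cand)
            if not (0.1 < c[0] < 0.9 and 0.1 < c[1] < 0.9):
                continue
            clear = True
            for v, cross in crossings.items():
                col, row = _projected_point(c, v, G)
                for ccol, crow, csize in cross:
                    if math.hypot(col - ccol, row - crow) < 3.5 * dome_r * G + csize:
                        clear = False
            for prev in centers:
                if np.linalg.norm(prev - c) < 8 * dome_r:
                    clear = False
            if clear:
                ok = cand
                break
        if ok is None:
            return None
        placed.append(ok)
        centers.append(_dome_center(curves[ok.curve_id], ok))
    return placed


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _attenuate(
    chord: np.ndarray, gain_k: float, washin: float, noise_sd: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    img = BACKGROUND - washin * gain_k * chord
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an RNG")
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_views(
    scene: SyntheticScene,
    *,
    washin: float = 1.0,
    frame_index: int = 0,
) -> tuple[GrayImage, GrayImage, dict[View, ViewTruth]]:
    """Render the region-only (288x288) frontal and lateral frames.

    Noise is drawn from a substream keyed by (scene seed, frame, view), so a
    fixed seed reproduces every frame byte-for-byte.
    """
    maps = chord_maps(scene)
    truth = scene_truth(scene)
    imgs = {}
    for vi, v in enumerate(View):
        rng = np.random.default_rng([scene.seed % (2**31), frame_index, vi])
        imgs[v] = GrayImage(
            _attenuate(maps[v], scene.gain_k, washin, scene.noise_sd, rng)
        )
    return imgs[View.FRONTAL], imgs[View.LATERAL], truth


def render_full_views(
    scene: SyntheticScene,
    *,
    washin: float = 1.0,
    frame_index: int = 0,
) -> tuple[GrayImage, GrayImage, dict[View, ViewTruth]]:
    """Render full frames with the region window embedded in a bright canvas."""
    maps = chord_maps(scene)
    truth = scene_truth(scene)
    imgs = {}
    for vi, v in enumerate(View):
        full_chord = np.zeros((scene.full_size, scene.full_size))
        ox, oy = scene.region_offsets[v]
        G = scene.region_size
        full_chord[oy:oy + G, ox:ox + G] = maps[v]
        rng = np.random.default_rng([scene.seed % (2**31), frame_index, vi])
        imgs[v] = GrayImage(
            _attenuate(full_chord, scene.gain_k, washin, scene.noise_sd, rng)
        )
    return imgs[View.FRONTAL], imgs[View.LATERAL], truth


def default_washin(n_frames: int) -> Callable[[int], float]:
    """Contrast wash-in: linear rise over the first third, then plateau at 1."""
    n_rise = max(1, math.ceil(n_frames / 3))

    def profile(j: int) -> float:
        return min(1.0, (j + 1) / n_rise)

    return profile


def render_sequence(
    scene: SyntheticScene,
    n_frames: int,
    *,
    washin: Callable[[int], float] | None = None,
    full_frame: bool = True,
    patient_id: str = "patient_0",
) -> PatientRecord:
    """Render an ordered biplane sequence as a :class:`PatientRecord`.

    Ground truth is constant across frames; ``truth_diagnosis`` is true iff
    the scene contains at least one aneurysm.  Frame counts of 6-12 match
    typical radiologist-selected wash-in windows.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    profile = washin or default_washin(n_frames)
    renderer = render_full_views if full_frame else render_views
    frames: list[FramePair] = []
    truth: dict[View, ViewTruth] = {}
    for j in range(n_frames):
        fr, la, truth = renderer(scene, washin=profile(j), frame_index=j)
        frames.append(FramePair(patient_id, j, fr, la))
    boxes_per_view = {v: truth[v].labeled_boxes() for v in View}
    return PatientRecord(
        patient_id=patient_id,
        frames=frames,
        truth_diagnosis=len(scene.aneurysms) > 0,
        truth_boxes={j: boxes_per_view for j in range(n_frames)},
    )


def write_patient_dir(
    record: PatientRecord,
    truth: dict[View, ViewTruth],
    out_dir: str | Path,
) -> None:
    """Write patient_<id>/{frontal,lateral}/frame_<j>.png plus annotations.csv."""
    from .core_types import AnnotationRecord, save_image, write_annotations

    out_dir = Path(out_dir)
    recs = []
    for pair in record.frames:
        for v in View:
            vdir = out_dir / v.value
            vdir.mkdir(parents=True, exist_ok=True)
            save_image(pair.view(v), vdir / f"frame_{pair.frame_index}.png")
    for v in View:
        for label, box in truth[v].labeled_boxes():
            recs.append(
                AnnotationRecord(record.patient_id, 0, v, label, box, None)
            )
    write_annotations(recs, out_dir / "annotations.csv")


def scene_to_json(scene: SyntheticScene) -> dict:
    """Scene provenance (parameters only, not voxel data) for scene.json."""
    return {
        "seed": scene.seed,
        "n_vessels": len(scene.curves),
        "region_size": scene.region_size,
        "full_size": scene.full_size,
        "gain_k": scene.gain_k,
        "noise_sd": scene.noise_sd,
        "region_offsets": {v.value: list(scene.region_offsets[v]) for v in View},
        "aneurysms": [
            dataclasses.asdict(a) for a in scene.aneurysms
        ],
    }
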