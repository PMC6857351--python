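"""End-to-end orchestration: localize -> detect -> retain -> suppress -> diagnose.

The pipeline mirrors the two-stage design: a region localization stage (RLS)
crops each full frame to the 288x288 region interface, the aneurysm
detection stage (ADS) runs the dual-view detector on the crops and keeps
candidates above the retention threshold, the grayscale suppression rule
(RAGS) relabels low-confidence aneurysms that are darker than their
surround, and the patient-level OR/max aggregation produces the diagnosis
and disease confidence.

Everything is driven by a single declarative :class:`PipelineConfig` that
round-trips losslessly through JSON; reports echo the effective config for
provenance and are byte-stable under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .candidate_detection import (
    RETENTION_THRESHOLD,
    ReferenceDetector,
    detect_candidates,
    make_dual_inputs,
    retain_confident,
)
from .core_types import (
    Detection,
    GrayImage,
    Label,
    PatientRecord,
    View,
    load_image,
    read_annotations,
)
from .evaluation import (
    PatientEvaluation,
    aggregate_patient,
    confusion,
    metrics,
    roc_auc,
    threshold_distribution,
)
from .rags import RagsConfig, SuppressionAction, apply_rags
from .region_localization import ReferenceLocalizer, localize
from .synthetic_dsa import (
    SyntheticScene,
    generate_scene,
    render_sequence,
    scene_to_json,
    scene_truth,
    write_patient_dir,
)

__all__ = [
    "PipelineConfig",
    "PatientResult",
    "run_patient",
    "run_cohort",
    "cohort_report",
    "iter_demo_cohort",
    "demo_cohort",
    "load_patient_dir",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the full pipeline."""

    use_rls: bool = True  # off for pre-cropped 288x288 inputs
    dual_view: bool = True
    retention_threshold: float = RETENTION_THRESHOLD
    rags_enabled: bool = True
    rags_c: float = 0.99
    rags_enlargement: float = 2.0
    rags_action: str = "relabel_overlap"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("retention_threshold", "rags_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def rags_config(self) -> RagsConfig:
        return RagsConfig(
            c=self.rags_c,
            enlargement_factor=self.rags_enlargement,
            action=SuppressionAction(self.rags_action),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class PatientResult:
    evaluation: PatientEvaluation
    #: frame index -> view -> retained (post-RAGS) detections, crop coordinates
    detections: dict[int, dict[View, list[Detection]]]


def run_patient(
    record: PatientRecord,
    config: PipelineConfig = PipelineConfig(),
    *,
    detector=None,
    localizer=None,
) -> PatientResult:
    """Run the full pipeline on one patient's biplane sequence."""
    detector = detector or ReferenceDetector(dual_view=config.dual_view)
    localizer = localizer or ReferenceLocalizer()
    rags_cfg = config.rags_config()
    all_dets: dict[int, dict[View, list[Detection]]] = {}
    for pair in record.frames:
        crops: dict[View, GrayImage | None] = {}
        for v in View:
            img = pair.view(v)
            if config.use_rls:
                res = localize(img, localizer)
                if res is None:
                    log.warning(
                        "patient %s frame %d %s: region not found; view skipped",
                        record.patient_id, pair.frame_index, v.value,
                    )
                crops[v] = res.crop if res is not None else None
            else:
                crops[v] = img
        duals = make_dual_inputs(
            pair, frontal=crops[View.FRONTAL], lateral=crops[View.LATERAL]
        )
        per_view: dict[View, list[Detection]] = {v: [] for v in View}
        for dual in duals:
            cands = detect_candidates(dual, detector)
            kept = retain_confident(cands, config.retention_threshold)
            if config.rags_enabled and kept:
                kept = apply_rags(kept, dual.target, rags_cfg)
            per_view[dual.target_view] = kept
        all_dets[pair.frame_index] = per_view
    evaluation = aggregate_patient(
        record.patient_id, all_dets, record.truth_diagnosis
    )
    return PatientResult(evaluation=evaluation, detections=all_dets)


def run_cohort(
    records: Iterator[PatientRecord] | list[PatientRecord],
    config: PipelineConfig = PipelineConfig(),
    *,
    detector=None,
    localizer=None,
) -> list[PatientResult]:
    return [
        run_patient(r, config, detector=detector, localizer=localizer)
        for r in records
    ]


def cohort_report(results: list[PatientResult], config: PipelineConfig) -> dict:
    """JSON-ready cohort summary: confusion matrix, metrics, ROC/AUC."""
    evals = [r.evaluation for r in results]
    cm = confusion(evals)
    report: dict = {
        "config": json.loads(config.to_json()),
        "n_patients": len(evals),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "patients": [
            {
                "patient_id": ev.patient_id,
                "truth": ev.truth,
                "diag_predicted": ev.diag_predicted,
                "disease_confidence": round(ev.disease_confidence, 9),
            }
            for ev in evals
        ],
    }
    try:
        sens, spec, acc = metrics(cm)
        report["metrics"] = {
            "sensitivity": sens, "specificity": spec, "accuracy": acc,
        }
    except ZeroDivisionError:
        report["metrics"] = None
    truths = {ev.truth for ev in evals}
    if truths == {True, False}:
        points, auc = roc_auc(evals)
        report["roc"] = {"points": points, "auc": auc}
    grid = [round(0.05 * i, 2) for i in range(21)]
    report["threshold_distribution"] = [
        {"c": c, "ge": ge, "lt": lt}
        for c, ge, lt in threshold_distribution(evals, grid)
    ]
    return report


# ---------------------------------------------------------------------------
# demo cohort
# ---------------------------------------------------------------------------


def iter_demo_cohort(
    seed: int,
    n_positive: int = 20,
    n_negative: int = 20,
    *,
    noise_sd: float = 2.0,
    full_frame: bool = True,
) -> Iterator[tuple[PatientRecord, SyntheticScene]]:
    """Lazily generate a balanced synthetic cohort.

    Patients alternate positive/negative until one class is exhausted; each
    has 2-4 vessels and a 6-12 frame biplane sequence, positives with one
    aneurysm.  Sub-seeds derive deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = [True] * n_positive + [False] * n_negative
    for i, positive in enumerate(labels):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        n_vessels = int(rng.integers(2, 5))
        n_frames = int(rng.integers(6, 13))
        scene = generate_scene(
            n_vessels=n_vessels,
            n_aneurysms=1 if positive else 0,
            seed=sub_seed,
            noise_sd=noise_sd,
        )
        pid = f"p{i:03d}_{'pos' if positive else 'neg'}"
        record = render_sequence(
            scene, n_frames, full_frame=full_frame, patient_id=pid
        )
        yield record, scene


def demo_cohort(seed: int, out_dir: str | Path, **kwargs) -> list[Path]:
    """Materialize the demo cohort as a directory tree with annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for record, scene in iter_demo_cohort(seed, **kwargs):
        pdir = out_dir / f"patient_{record.patient_id}"
        write_patient_dir(record, scene_truth(scene), pdir)
        (pdir / "scene.json").write_text(
            json.dumps(scene_to_json(scene), indent=1, sort_keys=True)
        )
        paths.append(pdir)
    return paths


# ---------------------------------------------------------------------------
# directory loading (CLI plumbing)
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


def load_patient_dir(pdir: str | Path) -> PatientRecord:
    """Load a patient directory written by the simulator or ``simulate`` CLI.

    Layout: ``<pdir>/{frontal,lateral}/frame_<j>.png`` plus
    ``annotations.csv``.  Frontal and lateral sequences are paired by frame
    index; unequal lengths are truncated to the shorter one with a warning.
    """
    pdir = Path(pdir)
    patient_id = pdir.name.removeprefix("patient_")
    frames_by_view: dict[View, dict[int, GrayImage]] = {}
    for v in View:
        vdir = pdir / v.value
        frames = {}
        for f in sorted(vdir.glob("frame_*.png")):
            m = _FRAME_RE.search(f.name)
            if m:
                frames[int(m.group(1))] = load_image(f)
        frames_by_view[v] = frames
    nf, nl = len(frames_by_view[View.FRONTAL]), len(frames_by_view[View.LATERAL])
    if nf != nl:
        log.warning(
            "patient %s: frontal has %d frames, lateral %d; pairing by index "
            "and truncating to the shorter sequence", patient_id, nf, nl,
        )
    common = sorted(
        set(frames_by_view[View.FRONTAL]) & set(frames_by_view[View.LATERAL])
    )
    if not common:
        raise ValueError(f"{pdir}: no paired frames")
    from .core_types import FramePair

    pairs = [
        FramePair(
            patient_id, j,
            frames_by_view[View.FRONTAL][j], frames_by_view[View.LATERAL][j],
        )
        for j in common
    ]
    truth_diagnosis = False
    truth_boxes: dict[int, dict[View, list[tuple[Label, object]]]] = {}
    ann_path = pdir / "annotations.csv"
    if ann_path.exists():
        for rec in read_annotations(ann_path):
            if rec.label is Label.ANEURYSM:
                truth_diagnosis = True
            truth_boxes.setdefault(rec.frame_index, {}).setdefault(
                rec.view, []
            ).append((rec.label, rec.box))
    return PatientRecord(
        patient_id=patient_id,
        frames=pairs,
        truth_diagnosis=truth_diagnosis,
        truth_boxes=truth_boxes,  # type: ignore[arg-type]
    )
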