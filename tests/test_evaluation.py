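import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsadetect.core_types import BoundingBox, Detection, Label, View
from dsadetect.evaluation import (
    ConfusionMatrix,
    PatientEvaluation,
    UndefinedMetricError,
    aggregate_patient,
    confusion,
    metrics,
    roc_auc,
    threshold_distribution,
)


def det(conf, label=Label.ANEURYSM):
    return Detection(BoundingBox(0, 0, 5, 5), label, conf)


def auc_mann_whitney(evals):
    """Pairwise concordance oracle: ties count one half."""
    pos = [e.disease_confidence for e in evals if e.truth]
    neg = [e.disease_confidence for e in evals if not e.truth]
    score = 0.0
    for p in pos:
        for n in neg:
            score += 1.0 if p > n else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


class TestAggregatePatient:
    def test_all_frames_negative(self):
        dets = {j: {v: [] for v in View} for j in range(6)}
        ev = aggregate_patient("p", dets, truth=False)
        assert ev.diag_predicted is False and ev.disease_confidence == 0.0

    def test_single_lateral_detection(self):
        dets = {j: {v: [] for v in View} for j in range(6)}
        dets[3][View.LATERAL] = [det(0.8)]
        ev = aggregate_patient("p", dets, truth=True)
        assert ev.diag_predicted is True and ev.disease_confidence == 0.8

    def test_overlap_labels_do_not_diagnose(self):
        dets = {0: {View.FRONTAL: [det(0.9, Label.OVERLAP)], View.LATERAL: []}}
        ev = aggregate_patient("p", dets, truth=False)
        assert ev.diag_predicted is False and ev.disease_confidence == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient("p", {}, truth=False)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_or_max_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = {}
        for j in range(20):
            dets[j] = {
                v: [det(float(np.round(rng.random(), 6)))
                    for _ in range(rng.integers(0, 3))]
                for v in View
            }
        ev = aggregate_patient("p", dets, truth=True)
        flat = [
            d.confidence
            for per_view in dets.values()
            for ds in per_view.values()
            for d in ds
        ]
        assert ev.diag_predicted == (len(flat) > 0)
        assert ev.disease_confidence == (max(flat) if flat else 0.0)

    def test_adding_detection_never_lowers_confidence(self):
        dets = {0: {View.FRONTAL: [det(0.7)], View.LATERAL: []}}
        base = aggregate_patient("p", dets, truth=True)
        dets[0][View.LATERAL] = [det(0.4)]
        more = aggregate_patient("p", dets, truth=True)
        assert more.diag_predicted >= base.diag_predicted
        assert more.disease_confidence >= base.disease_confidence


def _cohort(tp, fp, tn, fn):
    evs = []
    for i in range(tp):
        evs.append(PatientEvaluation(f"tp{i}", True, 0.9, True))
    for i in range(fp):
        evs.append(PatientEvaluation(f"fp{i}", True, 0.8, False))
    for i in range(tn):
        evs.append(PatientEvaluation(f"tn{i}", False, 0.0, False))
    for i in range(fn):
        evs.append(PatientEvaluation(f"fn{i}", False, 0.0, True))
    return evs


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        cm = confusion(_cohort(3, 0, 4, 0))
        assert cm.fp == 0 and cm.fn == 0

    def test_forty_patient_cohort_reconstruction(self):
        cm = confusion(_cohort(19, 14, 6, 1))
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (19, 14, 6, 1)

    def test_counts_conserve_cohort_size(self):
        evs = _cohort(5, 3, 7, 2)
        assert confusion(evs).total == len(evs)


class TestMetrics:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            # baseline classical method: 40-patient confusion (19, 14, 6, 1)
            (ConfusionMatrix(19, 14, 6, 1), (0.950, 0.300, 0.625)),
            # dual-input detector without suppression (fold-averaged counts)
            (ConfusionMatrix(20, 11, 9, 0), (1.000, 0.450, 0.725)),
            # dual-input + grayscale suppression (fold-averaged counts)
            (ConfusionMatrix(19.2, 1.8, 18.2, 0.8), (0.960, 0.910, 0.935)),
            (ConfusionMatrix(10, 0, 10, 0), (1.0, 1.0, 1.0)),
        ],
    )
    def test_sensitivity_specificity_accuracy(self, cm, expected):
        sens, spec, acc = metrics(cm)
        assert round(sens, 3) == expected[0]
        assert round(spec, 3) == expected[1]
        assert round(acc, 3) == expected[2]

    def test_accuracy_identity(self):
        cm = ConfusionMatrix(7, 3, 11, 2)
        assert metrics(cm)[2] == pytest.approx((7 + 11) / 23)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionMatrix(0, 2, 3, 0))  # no positives
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionMatrix(2, 0, 0, 1))  # no negatives


class TestRocAuc:
    def test_perfect_separation(self):
        evs = [PatientEvaluation(f"p{i}", True, 0.9, True) for i in range(4)]
        evs += [PatientEvaluation(f"n{i}", False, 0.1, False) for i in range(4)]
        _, auc = roc_auc(evs)
        assert auc == pytest.approx(1.0)

    def test_uninformative_confidences_give_chance_auc(self):
        evs = [PatientEvaluation(f"p{i}", True, 0.5, i < 3) for i in range(6)]
        _, auc = roc_auc(evs)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        evs = [PatientEvaluation("p", True, 0.5, True)]
        with pytest.raises(ValueError):
            roc_auc(evs)

    @settings(max_examples=120, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_mann_whitney_oracle_on_small_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        truths = rng.random(n) < 0.5
        if truths.all() or not truths.any():
            truths[0] = True
            truths[-1] = False
        # coarse confidences force plenty of ties
        confs = rng.integers(0, 4, size=n) / 3.0
        evs = [
            PatientEvaluation(f"p{i}", bool(confs[i] > 0.5), float(confs[i]), bool(truths[i]))
            for i in range(n)
        ]
        _, auc = roc_auc(evs)
        assert auc == pytest.approx(auc_mann_whitney(evs))


class TestThresholdDistribution:
    def test_buckets_partition_cohort(self):
        evs = _cohort(5, 2, 6, 1)
        for c, ge, lt in threshold_distribution(evs, [0.0, 0.5, 0.85, 1.01]):
            assert ge + lt == len(evs)

    def test_extreme_thresholds(self):
        evs = _cohort(3, 1, 3, 1)
        dist = threshold_distribution(evs, [0.0, 1.01])
        assert dist[0][1] == len(evs)  # c=0: everyone >=
        assert dist[1][2] == len(evs)  # c>1: everyone <
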