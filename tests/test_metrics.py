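"""Evaluation metrics: P/R/F1 arithmetic, IoU, matching, AP, counting rates."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from cagecount.metrics import (
    CountingReport,
    UndefinedMetricWarning,
    ap_50_95,
    as_percent,
    average_precision,
    chicken_recognition_rate,
    chicken_selection_rate,
    f1,
    iou,
    match_detections,
    precision,
    recall,
    sample_selection_rate,
    split_counts,
)
from cagecount.types import Detection


# ---------------------------------------------------------------------------
# independent reference AP (plain loops, own IoU) used as the oracle

def _ref_iou(a, b):
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    if w <= 0 or h <= 0:
        return 0.0
    inter = w * h
    union = (
        (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    )
    return inter / union


def reference_ap(preds_by_frame, truths_by_frame, thr):
    """101-point interpolated AP for a single class, written as directly as
    possible from the definition."""
    flags = []  # (confidence, matched?)
    n_truth = 0
    for key in sorted(set(preds_by_frame) | set(truths_by_frame), key=str):
        preds = sorted(
            preds_by_frame.get(key, []), key=lambda d: -d.confidence
        )
        truths = list(truths_by_frame.get(key, []))
        n_truth += len(truths)
        used = set()
        for p in preds:
            best, best_val = None, 0.0
            for j, t in enumerate(truths):
                if j in used:
                    continue
                v = _ref_iou(p.box, t.box)
                if v >= thr and v > best_val:
                    best, best_val = j, v
            if best is not None:
                used.add(best)
                flags.append((p.confidence, True))
            else:
                flags.append((p.confidence, False))
    if n_truth == 0:
        return 0.0
    flags.sort(key=lambda x: -x[0])
    prec, rec = [], []
    tp = fp = 0
    for _, good in flags:
        if good:
            tp += 1
        else:
            fp += 1
        prec.append(tp / (tp + fp))
        rec.append(tp / n_truth)
    total = 0.0
    for level in np.linspace(0, 1, 101):
        best = 0.0
        for p, r in zip(prec, rec):
            if r >= level and p > best:
                best = p
        total += best
    return total / 101


def random_frame_sets(seed, n_frames=4, boxes_per_frame=5, miss=0.3):
    """A small multi-frame prediction/truth benchmark with jittered preds."""
    rng = np.random.default_rng(seed)
    preds, truths = {}, {}
    for f in range(n_frames):
        t_list, p_list = [], []
        for _ in range(boxes_per_frame):
            x, y = rng.uniform(0, 1100, 2)
            w, h = rng.uniform(40, 120, 2)
            t_list.append(Detection("chicken_head", (x, y, x + w, y + h)))
            if rng.random() > miss:
                dx, dy = rng.normal(0, 12, 2)
                p_list.append(
                    Detection(
                        "chicken_head",
                        (x + dx, y + dy, x + w + dx, y + h + dy),
                        float(rng.uniform(0.3, 1.0)),
                    )
                )
        for _ in range(rng.poisson(1.0)):
            x, y = rng.uniform(0, 1100, 2)
            p_list.append(
                Detection(
                    "chicken_head",
                    (x, y, x + 80, y + 80),
                    float(rng.uniform(0.3, 1.0)),
                )
            )
        preds[f], truths[f] = p_list, t_list
    return preds, truths


# ---------------------------------------------------------------------------

class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "p, r, expected_pct",
        [(0.974, 0.960, 96.7), (0.925, 0.949, 93.7)],
    )
    def test_f1_reproduces_printed_model_comparison(self, p, r, expected_pct):
        assert as_percent(f1(p, r)) == expected_pct

    def test_precision_recall_definitions(self):
        assert precision(90, 10) == pytest.approx(0.9)
        assert recall(90, 30) == pytest.approx(0.75)

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UndefinedMetricWarning):
            assert precision(0, 0) == 0.0
        with pytest.warns(UndefinedMetricWarning):
            assert f1(0.0, 0.0) == 0.0

    def test_negative_counts_rejected(self):
        from cagecount.errors import ContractError

        with pytest.raises(ContractError):
            precision(-1, 5)

    @settings(max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.001, 1.0),
        r=st.floats(0.001, 1.0),
    )
    def test_mean_inequality_chain(self, p, r):
        harmonic = f1(p, r)
        geometric = (p * r) ** 0.5
        arithmetic = (p + r) / 2
        assert harmonic <= geometric + 1e-12
        assert geometric <= arithmetic + 1e-12


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_partial_overlap_area_arithmetic(self):
        # inter = 1x2 = 2; union = 4 + 4 - 2 = 6
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(2 / 6)

    def test_touching_boxes_have_zero_iou(self):
        assert iou((0, 0, 10, 10), (10, 0, 20, 10)) == 0.0


class TestMatching:
    def test_exact_match(self):
        t = [Detection("chicken_head", (10, 10, 60, 60))]
        p = [Detection("chicken_head", (10, 10, 60, 60), 0.9)]
        res = match_detections(p, t, 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.matched_pairs[0][2] == pytest.approx(1.0)

    def test_duplicate_predictions_higher_confidence_wins(self):
        t = [Detection("chicken_head", (10, 10, 60, 60))]
        p = [
            Detection("chicken_head", (12, 12, 62, 62), 0.6),
            Detection("chicken_head", (10, 10, 60, 60), 0.9),
        ]
        res = match_detections(p, t, 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.matched_pairs == [(1, 0, pytest.approx(1.0))]

    def test_bookkeeping_invariants(self):
        preds, truths = random_frame_sets(0)
        res = match_detections(preds[0], truths[0], 0.5)
        assert res.tp == len(res.matched_pairs)
        assert res.tp + res.fn == len(truths[0])
        assert res.tp + res.fp == len(preds[0])
        assert res.sorted_confidences == sorted(
            (p.confidence for p in preds[0]), reverse=True
        )

    def test_greedy_tp_close_to_optimal_assignment(self):
        """Greedy matching vs the exhaustive optimal assignment (Hungarian)
        on random 6-box instances: within 1 true positive."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            boxes = rng.uniform(0, 200, size=(6, 2))
            sizes = rng.uniform(30, 90, size=(6, 2))
            truths = [
                Detection("chicken_head", (x, y, x + w, y + h))
                for (x, y), (w, h) in zip(boxes, sizes)
            ]
            preds = []
            for (x, y), (w, h) in zip(boxes + rng.normal(0, 25, (6, 2)), sizes):
                preds.append(
                    Detection(
                        "chicken_head",
                        (x, y, x + w, y + h),
                        float(rng.uniform(0, 1)),
                    )
                )
            matrix = np.array(
                [[iou(p.box, t.box) for t in truths] for p in preds]
            )
            feasible = (matrix >= 0.5).astype(float)
            rows, cols = linear_sum_assignment(-feasible)
            optimal_tp = int(feasible[rows, cols].sum())
            greedy_tp = match_detections(preds, truths, 0.5).tp
            assert abs(greedy_tp - optimal_tp) <= 1


class TestAveragePrecision:
    def test_perfect_detections_give_ap_1(self):
        _, truths = random_frame_sets(1, miss=0.0)
        perfect = {
            k: [Detection(d.label, d.box, 0.9) for d in v]
            for k, v in truths.items()
        }
        assert ap_50_95(perfect, truths) == pytest.approx(1.0)

    def test_all_false_positives_give_ap_0(self):
        truths = {0: [Detection("chicken_head", (10, 10, 60, 60))]}
        preds = {0: [Detection("chicken_head", (500, 500, 560, 560), 0.9)]}
        assert ap_50_95(preds, truths) == 0.0

    def test_no_truths_warns(self):
        preds = {0: [Detection("chicken_head", (1, 1, 5, 5), 0.5)]}
        with pytest.warns(UndefinedMetricWarning):
            assert average_precision(preds, {0: []}, 0.5) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_reference_implementation(self, seed):
        preds, truths = random_frame_sets(seed)
        for thr in (0.5, 0.75, 0.95):
            expected = reference_ap(preds, truths, thr)
            assert average_precision(preds, truths, thr) == pytest.approx(
                expected, abs=1e-4
            )
        expected_5095 = np.mean(
            [reference_ap(preds, truths, t) for t in np.arange(0.5, 0.96, 0.05)]
        )
        assert ap_50_95(preds, truths) == pytest.approx(expected_5095, abs=1e-4)

    def test_invariant_to_monotone_confidence_rescaling(self):
        preds, truths = random_frame_sets(3)
        rescaled = {
            k: [Detection(d.label, d.box, d.confidence**3) for d in v]
            for k, v in preds.items()
        }
        assert average_precision(rescaled, truths, 0.5) == pytest.approx(
            average_precision(preds, truths, 0.5)
        )


class TestCountingRates:
    @pytest.mark.parametrize(
        "fn, num, den, expected_pct",
        [
            (sample_selection_rate, 344, 650, 52.9),
            (sample_selection_rate, 336, 650, 51.7),
            (chicken_selection_rate, 1554, 3838, 40.5),
            (chicken_selection_rate, 1480, 3733, 39.6),
            (chicken_recognition_rate, 448, 493, 90.9),
            (chicken_recognition_rate, 216, 244, 88.5),
            (chicken_recognition_rate, 232, 249, 93.2),
            (chicken_recognition_rate, 383, 493, 77.7),
            (chicken_recognition_rate, 182, 244, 74.6),
            (chicken_recognition_rate, 201, 249, 80.7),
        ],
    )
    def test_printed_field_trial_rates(self, fn, num, den, expected_pct):
        assert as_percent(fn(num, den)) == expected_pct

    def test_degenerate_rates(self):
        assert sample_selection_rate(0, 650) == 0.0
        assert chicken_selection_rate(100, 100) == 1.0
        assert chicken_recognition_rate(0, 500) == 0.0

    def test_counting_report_consistency(self):
        report = CountingReport(
            initial_samples=650,
            complete_cage_samples=650,
            samples_after_threshold=344,
            actual_chickens=4017,
            detected_chickens=3838,
            chickens_after_threshold=1554,
        )
        assert report.sample_selection_rate == pytest.approx(344 / 650, abs=1e-9)
        assert report.as_percent_dict() == {
            "sample_selection_rate": 52.9,
            "chicken_selection_rate": 40.5,
            "chicken_recognition_rate": 95.5,
        }


def test_dataset_split_8_1_1():
    assert split_counts(6500, (8, 1, 1)) == (5200, 650, 650)
    assert sum(split_counts(6501, (8, 1, 1))) == 6501
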