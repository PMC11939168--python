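"""Detection and counting evaluation statistics.

Detection quality is summarised by precision P = TP/(TP+FP), recall
R = TP/(TP+FN), their harmonic mean F1 = 2PR/(P+R), and average precision
integrated over the precision–recall curve, reported both at a single IoU
threshold (AP50) and averaged over IoU in {0.50, 0.55, ..., 0.95}
(AP50:95).  AP uses 101-point interpolation: precision is enveloped from
the right and sampled at recall levels 0, 0.01, ..., 1.

Counting quality uses three ratios: the sample selection rate (frames kept
by threshold processing over frames showing a complete cage), the chicken
selection rate (heads assigned to the cage over all heads detected in the
frame), and the chicken recognition rate (heads detected in the cage over
the manually verified true count).

Zero-denominator ratios are defined as 0 and raise
:class:`UndefinedMetricWarning` instead of aborting, so batch evaluation
always completes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError
from .types import Detection, DetectionStream

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_LEVELS = np.linspace(0.0, 1.0, 101)


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; the value is reported as 0."""


def _ratio(num: float, den: float, name: str) -> float:
    if num < 0 or den < 0:
        raise ContractError(f"{name}: counts must be non-negative")
    if den == 0:
        warnings.warn(
            f"{name} undefined (zero denominator); reporting 0",
            UndefinedMetricWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def precision(tp: int, fp: int) -> float:
    """P = TP / (TP + FP)."""
    return _ratio(tp, tp + fp, "precision")


def recall(tp: int, fn: int) -> float:
    """R = TP / (TP + FN)."""
    return _ratio(tp, tp + fn, "recall")


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ContractError("precision and recall must lie in [0, 1]")
    return _ratio(2.0 * p * r, p + r, "f1")


def sample_selection_rate(after: int, complete: int) -> float:
    """Frames kept by threshold processing / frames with a complete cage."""
    return _ratio(after, complete, "sample_selection_rate")


def chicken_selection_rate(after: int, detected: int) -> float:
    """Heads assigned to the cage / all heads detected in the frame set."""
    return _ratio(after, detected, "chicken_selection_rate")


def chicken_recognition_rate(detected: int, actual: int) -> float:
    """Heads detected in cages / manually verified true head count."""
    return _ratio(detected, actual, "chicken_recognition_rate")


def as_percent(fraction: float, ndigits: int = 1) -> float:
    """Percentage with round-half-up at ``ndigits`` decimals (printed-table
    convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, ROUND_HALF_UP))


def split_counts(total: int, ratios: Sequence[int] = (8, 1, 1)) -> tuple[int, ...]:
    """Partition a dataset of ``total`` items by integer ratio parts.

    Largest-remainder apportionment, so the parts always sum to ``total``;
    6500 at 8:1:1 gives (5200, 650, 650).
    """
    if total < 0 or any(r <= 0 for r in ratios):
        raise ContractError("total must be >= 0 and ratios positive")
    denom = sum(ratios)
    raw = [total * r / denom for r in ratios]
    base = [int(x) for x in raw]
    remainder = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:remainder]:
        base[i] += 1
    return tuple(base)


# ---------------------------------------------------------------------------
# box matching

def iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two corner boxes; 0 when disjoint."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


@dataclass
class MatchResult:
    """Outcome of matching one frame's predictions against its truths."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    sorted_confidences: list[float] = field(default_factory=list)


def match_detections(
    preds: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching within one frame and class.

    Predictions are visited in descending confidence; each claims the
    highest-IoU still-unmatched truth with IoU at or above the threshold.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    taken = [False] * len(truths)
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        best_j, best_val = -1, 0.0
        for tj, truth in enumerate(truths):
            if taken[tj]:
                continue
            val = iou(preds[pi].box, truth.box)
            if val >= iou_threshold and val > best_val:
                best_j, best_val = tj, val
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((pi, best_j, best_val))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(truths) - tp,
        matched_pairs=pairs,
        sorted_confidences=sorted((p.confidence for p in preds), reverse=True),
    )


# ---------------------------------------------------------------------------
# average precision

FrameSets = Mapping[object, Sequence[Detection]]


def _as_frame_dict(obj: "DetectionStream | FrameSets") -> dict[object, list[Detection]]:
    if isinstance(obj, DetectionStream):
        return {f.frame_index: list(f.detections) for f in obj.frames}
    return {k: list(v) for k, v in obj.items()}


def _class_labels(*sets: dict[object, list[Detection]]) -> list[str]:
    labels = set()
    for s in sets:
        for dets in s.values():
            labels.update(d.label for d in dets)
    return sorted(labels)


def _ap_single_class(
    preds: dict[object, list[Detection]],
    truths: dict[object, list[Detection]],
    iou_threshold: float,
) -> float:
    n_truth = sum(len(v) for v in truths.values())
    if n_truth == 0:
        warnings.warn(
            "average precision undefined without ground truth; reporting 0",
            UndefinedMetricWarning,
            stacklevel=3,
        )
        return 0.0
    scored: list[tuple[float, bool]] = []  # (confidence, is_tp)
    for key in set(preds) | set(truths):
        p = preds.get(key, [])
        t = truths.get(key, [])
        result = match_detections(p, t, iou_threshold)
        matched = {pi for pi, _, _ in result.matched_pairs}
        for pi, det in enumerate(p):
            scored.append((det.confidence, pi in matched))
    if not scored:
        return 0.0
    scored.sort(key=lambda x: -x[0])
    tp_cum = np.cumsum([s[1] for s in scored])
    fp_cum = np.cumsum([not s[1] for s in scored])
    rec = tp_cum / n_truth
    prec = tp_cum / (tp_cum + fp_cum)
    # envelope precision from the right, sample at 101 recall levels
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    idx = np.searchsorted(rec, RECALL_LEVELS, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(sampled.mean())


def average_precision(
    preds: "DetectionStream | FrameSets",
    truths: "DetectionStream | FrameSets",
    iou_threshold: float = 0.5,
) -> float:
    """Class-mean AP at one IoU threshold over a multi-frame set."""
    p, t = _as_frame_dict(preds), _as_frame_dict(truths)
    labels = _class_labels(t) or _class_labels(p)
    if not labels:
        return 0.0
    vals = []
    for label in labels:
        pl = {k: [d for d in v if d.label == label] for k, v in p.items()}
        tl = {k: [d for d in v if d.label == label] for k, v in t.items()}
        vals.append(_ap_single_class(pl, tl, iou_threshold))
    return float(np.mean(vals))


def ap_50_95(
    preds: "DetectionStream | FrameSets",
    truths: "DetectionStream | FrameSets",
) -> float:
    """Mean AP over IoU thresholds 0.50 to 0.95 in steps of 0.05."""
    return float(
        np.mean([average_precision(preds, truths, t) for t in IOU_THRESHOLDS_50_95])
    )


# ---------------------------------------------------------------------------
# counting report

@dataclass
class CountingReport:
    """The threshold-processing evaluation summary for one run."""

    initial_samples: int
    complete_cage_samples: int
    samples_after_threshold: int
    actual_chickens: int
    detected_chickens: int
    chickens_after_threshold: int
    sample_selection_rate: float = 0.0
    chicken_selection_rate: float = 0.0
    chicken_recognition_rate: float = 0.0

    def __post_init__(self) -> None:
        self.sample_selection_rate = sample_selection_rate(
            self.samples_after_threshold, self.complete_cage_samples
        )
        self.chicken_selection_rate = chicken_selection_rate(
            self.chickens_after_threshold, self.detected_chickens
        )
        self.chicken_recognition_rate = chicken_recognition_rate(
            self.detected_chickens, self.actual_chickens
        )

    def as_percent_dict(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "sample_selection_rate": as_percent(self.sample_selection_rate, ndigits),
            "chicken_selection_rate": as_percent(self.chicken_selection_rate, ndigits),
            "chicken_recognition_rate": as_percent(
                self.chicken_recognition_rate, ndigits
            ),
        }
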