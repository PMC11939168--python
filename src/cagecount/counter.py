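"""Cage-transition state machine and per-cage maximum counting.

The inspection camera traverses a row of cages; a cage is "in view" while
exactly two fence (railing) boxes are detected.  While that holds, heads
whose horizontal position falls inside the lateral span defined by the fence
pair are counted, and the running per-cage maximum is maintained.  When the
fence count drops below two, a consecutive-frame check decides between a
momentary detector dropout (streak < N: the running maximum is kept and
counting resumes) and a genuine cage transition (streak reaches N: the cage's
maximum count, key frame and timestamp are emitted and the state resets).
Frames with three or more fences are ignored: at the prescribed 50 cm
standoff at most one full cage is in view, so such frames are spurious.

Only horizontal coordinates participate in any decision; the vertical extent
of boxes is irrelevant to cage membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import ContractError, DegenerateSpanError
from .types import CageRecord, Detection, DetectionStream, FrameRecord, Span


class Phase(str, Enum):
    IDLE = "IDLE"            # no cage seen yet (or just emitted)
    COUNTING = "COUNTING"    # two fences stable, counting heads
    TRANSITION = "TRANSITION"  # fence count dropped; streak being checked


@dataclass(frozen=True)
class CounterConfig:
    """Tunable thresholds of the counting state machine.

    transition_frames
        N, the number of consecutive sub-two-fence frames that ends a cage
        (default 10; shorter bursts are treated as detector false negatives).
    confidence_min
        Detections below this score are discarded before any logic.
    span_mode
        ``outer``: envelope of both fence boxes (min of the x_mins to max of
        the x_maxes).  ``inner``: between the facing fence edges.
    membership
        ``center``: a head belongs to the cage if its x-center lies in the
        closed span.  ``full_box``: its whole box must lie inside.
    zero_fence_in_streak
        Whether zero-fence frames advance the transition streak once counting
        has begun (default true; otherwise they are ignored).
    """

    transition_frames: int = 10
    confidence_min: float = 0.25
    span_mode: str = "outer"
    membership: str = "center"
    zero_fence_in_streak: bool = True

    def __post_init__(self) -> None:
        if self.transition_frames < 1:
            raise ContractError("transition_frames must be >= 1")
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ContractError("confidence_min must lie in [0, 1]")
        if self.span_mode not in ("outer", "inner"):
            raise ContractError(f"unknown span_mode {self.span_mode!r}")
        if self.membership not in ("center", "full_box"):
            raise ContractError(f"unknown membership {self.membership!r}")


@dataclass
class CounterState:
    """Mutable context of the machine; one instance per inspection pass."""

    phase: Phase = Phase.IDLE
    running_max: int = 0
    key_frame_index: int | None = None
    key_timestamp_s: float | None = None
    single_fence_streak: int = 0
    cages_emitted: int = 0


def cage_span(fences: Sequence[Detection], mode: str = "outer") -> Span:
    """Lateral spatial threshold of the cage from exactly two fence boxes.

    ``outer`` returns the envelope of both boxes; ``inner`` the interval
    between the left fence's right edge and the right fence's left edge,
    where "left" is the fence with the smaller x-center.
    """
    if len(fences) != 2:
        raise ContractError(f"cage_span needs exactly 2 fences, got {len(fences)}")
    a, b = fences
    if mode == "outer":
        return Span(min(a.box[0], b.box[0]), max(a.box[2], b.box[2]))
    if mode == "inner":
        left, right = (a, b) if a.x_center <= b.x_center else (b, a)
        lo, hi = left.box[2], right.box[0]
        if lo >= hi:
            raise DegenerateSpanError(
                f"fences overlap in x: inner span ({lo}, {hi}) is empty"
            )
        return Span(lo, hi)
    raise ContractError(f"unknown span mode {mode!r}")


def heads_in_span(
    heads: Iterable[Detection], span: Span, membership: str = "center"
) -> list[Detection]:
    """Heads belonging to the cage; order preserved, interval closed."""
    if membership == "center":
        return [h for h in heads if span.x_low <= h.x_center <= span.x_high]
    if membership == "full_box":
        return [
            h for h in heads
            if h.box[0] >= span.x_low and h.box[2] <= span.x_high
        ]
    raise ContractError(f"unknown membership {membership!r}")


def filter_confidence(frame: FrameRecord, confidence_min: float) -> FrameRecord:
    """Copy of the frame keeping only detections at or above the threshold."""
    return FrameRecord(
        frame_index=frame.frame_index,
        timestamp_s=frame.timestamp_s,
        detections=[d for d in frame.detections if d.confidence >= confidence_min],
        image_size=frame.image_size,
    )


def step(
    state: CounterState, frame: FrameRecord, config: CounterConfig
) -> tuple[CounterState, CageRecord | None]:
    """Advance the machine by one (confidence-pre-filtered) frame.

    Returns the updated state and the cage record emitted on this frame, if
    any.  A record is emitted only on the frame where the transition streak
    reaches N.  The state object is mutated in place and also returned.
    """
    fences = frame.by_label("fence")
    n_fences = len(fences)

    if n_fences == 2:
        state.single_fence_streak = 0
        state.phase = Phase.COUNTING
        span = cage_span(fences, config.span_mode)
        count = len(
            heads_in_span(frame.by_label("chicken_head"), span, config.membership)
        )
        if state.key_frame_index is None:
            # first counting frame anchors the key frame for empty cages
            state.key_frame_index = frame.frame_index
            state.key_timestamp_s = frame.timestamp_s
        if count > state.running_max:
            state.running_max = count
            state.key_frame_index = frame.frame_index
            state.key_timestamp_s = frame.timestamp_s
        return state, None

    if n_fences >= 3:
        return state, None  # spurious frame; streak and counts untouched

    # zero or one fence in view
    if n_fences == 0 and not config.zero_fence_in_streak:
        return state, None
    if state.phase is Phase.IDLE:
        return state, None
    state.phase = Phase.TRANSITION
    state.single_fence_streak += 1
    if state.single_fence_streak == config.transition_frames:
        record = CageRecord(
            cage_id=state.cages_emitted + 1,
            max_count=state.running_max,
            key_frame_index=int(state.key_frame_index),  # type: ignore[arg-type]
            timestamp_s=float(state.key_timestamp_s),  # type: ignore[arg-type]
        )
        state.cages_emitted += 1
        state.running_max = 0
        state.key_frame_index = None
        state.key_timestamp_s = None
        state.single_fence_streak = 0
        state.phase = Phase.IDLE
        return state, record
    return state, None


def count_stream(
    stream: DetectionStream, config: CounterConfig | None = None
) -> list[CageRecord]:
    """Fold :func:`step` over a stream; cage ids are consecutive from 1.

    At end of stream a pending cage with a positive running maximum is
    flushed (the robot stops at the row end; the last cage would otherwise
    be lost).
    """
    config = config or CounterConfig()
    state = CounterState()
    records: list[CageRecord] = []
    for frame in stream:
        state, record = step(
            state, filter_confidence(frame, config.confidence_min), config
        )
        if record is not None:
            records.append(record)
    if state.phase is not Phase.IDLE and state.running_max > 0:
        records.append(
            CageRecord(
                cage_id=state.cages_emitted + 1,
                max_count=state.running_max,
                key_frame_index=int(state.key_frame_index),  # type: ignore[arg-type]
                timestamp_s=float(state.key_timestamp_s),  # type: ignore[arg-type]
            )
        )
    return records


def select_key_frame(stream: DetectionStream, record: CageRecord) -> FrameRecord:
    """The frame stored with a cage record: the earliest frame attaining the
    cage's maximum in-span head count."""
    for frame in stream:
        if frame.frame_index == record.key_frame_index:
            return frame
    raise ContractError(
        f"key frame {record.key_frame_index} not present in stream"
    )
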