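"""Shared fixtures and stream-building helpers."""

from __future__ import annotations

import pytest

from cagecount.types import Detection, DetectionStream, FrameRecord

# Fence boxes used by hand-built frames: a pair delimiting one cage.
LEFT_FENCE = (100.0, 0.0, 180.0, 700.0)
RIGHT_FENCE = (1050.0, 0.0, 1130.0, 700.0)
EXTRA_FENCE = (600.0, 0.0, 660.0, 700.0)


def head(cx: float, cy: float = 360.0, size: float = 60.0,
         confidence: float = 0.9) -> Detection:
    return Detection(
        "chicken_head",
        (cx - size / 2, cy - size / 2, cx + size / 2, cy + size / 2),
        confidence,
    )


def frame_with(fence_count: int, head_centers: list[float] = (),
               index: int = 0, fps: float = 30.0) -> FrameRecord:
    """A frame with the given number of fences and heads at given x-centers."""
    fences = [LEFT_FENCE, RIGHT_FENCE, EXTRA_FENCE][:fence_count]
    dets = [Detection("fence", f, 0.9) for f in fences]
    dets += [head(cx) for cx in head_centers]
    return FrameRecord(
        frame_index=index, timestamp_s=index / fps, detections=dets,
        image_size=(1280, 720),
    )


def stream_from_counts(
    fence_counts: list[int],
    head_counts: list[int] | None = None,
    fps: float = 30.0,
) -> DetectionStream:
    """Build a stream from per-frame fence counts and in-span head counts.

    Heads are placed well inside the fence pair, spread over [300, 900], so
    they are in-span under every span mode and membership rule.
    """
    head_counts = head_counts or [0] * len(fence_counts)
    frames = []
    for i, (fc, hc) in enumerate(zip(fence_counts, head_counts)):
        centers = [300.0 + 600.0 * k / max(1, hc) for k in range(hc)]
        frames.append(frame_with(fc, centers, index=i, fps=fps))
    return DetectionStream(frames=frames, fps=fps)


def oracle_emissions(
    fence_counts: list[int],
    n_threshold: int = 10,
    zero_fence_in_streak: bool = True,
) -> list[int]:
    """Brute-force interpreter of the transition flowchart on a fence-count
    sequence; returns the frame positions where a cage record is emitted.

    Kept deliberately simple and separate from the implementation: a scan
    for maximal runs of sub-two-fence frames following at least one
    two-fence frame since the last emission.
    """
    emitted: list[int] = []
    armed = False  # has a 2-fence frame been seen since the last emission?
    run = 0
    for i, fc in enumerate(fence_counts):
        if fc == 2:
            armed = True
            run = 0
        elif fc >= 3:
            continue
        else:  # 0 or 1 fences
            if fc == 0 and not zero_fence_in_streak:
                continue
            if not armed:
                continue
            run += 1
            if run == n_threshold:
                emitted.append(i)
                armed = False
                run = 0
    return emitted


@pytest.fixture
def fig11_frame():
    from cagecount.simulator import make_fig11_fixture

    return make_fig11_fixture()
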