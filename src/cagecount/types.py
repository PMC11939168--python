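"""Core domain types for detection streams and cage records.

Coordinates are continuous pixel floats, 0-based, origin at the top-left
corner with x increasing rightward; a box is the closed rectangle
``(x_min, y_min, x_max, y_max)``.  Only continuous overlap and membership
tests are performed downstream, so no half-open pixel semantics are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

from .errors import StreamValidationError

#: Recognised object classes: the chicken head (proxy for a live bird) and
#: the cage fence (railing); a visible fence pair delimits exactly one cage.
LABELS = ("chicken_head", "fence")


@dataclass(frozen=True)
class Detection:
    """One labeled, scored axis-aligned box in one frame."""

    label: str
    box: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise StreamValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        x_min, y_min, x_max, y_max = self.box
        if not (x_min < x_max and y_min < y_max):
            raise StreamValidationError(f"degenerate box {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise StreamValidationError(
                f"confidence {self.confidence} outside [0, 1]"
            )

    @property
    def x_center(self) -> float:
        return 0.5 * (self.box[0] + self.box[2])

    @property
    def width(self) -> float:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> float:
        return self.box[3] - self.box[1]

    def clamped(self, image_size: tuple[float, float]) -> "Detection | None":
        """Clamp the box to the frame; ``None`` if nothing remains inside."""
        w, h = image_size
        x0 = min(max(self.box[0], 0.0), w)
        y0 = min(max(self.box[1], 0.0), h)
        x1 = min(max(self.box[2], 0.0), w)
        y1 = min(max(self.box[3], 0.0), h)
        if x0 >= x1 or y0 >= y1:
            return None
        return Detection(self.label, (x0, y0, x1, y1), self.confidence)


@dataclass
class FrameRecord:
    """All detections of one frame plus its index, time, and frame size."""

    frame_index: int
    timestamp_s: float
    detections: list[Detection] = field(default_factory=list)
    image_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise StreamValidationError(
                f"frame_index {self.frame_index} must be non-negative"
            )

    def by_label(self, label: str) -> list[Detection]:
        return [d for d in self.detections if d.label == label]


@dataclass
class DetectionStream:
    """An ordered sequence of frames from a single inspection pass."""

    frames: list[FrameRecord]
    fps: float = 30.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise StreamValidationError(f"fps {self.fps} must be positive")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise StreamValidationError(
                "frame indices must be strictly increasing"
            )

    def __iter__(self) -> Iterator[FrameRecord]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Span:
    """The lateral (horizontal) pixel interval of one cage."""

    x_low: float
    x_high: float

    def __post_init__(self) -> None:
        if not self.x_low < self.x_high:
            raise StreamValidationError(
                f"span ({self.x_low}, {self.x_high}) is empty"
            )


@dataclass(frozen=True)
class CageRecord:
    """Per-cage output: ordinal id, max head count, key frame, time."""

    cage_id: int
    max_count: int
    key_frame_index: int
    timestamp_s: float
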