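"""Ground-truthed synthetic inspection streams.

The world is a one-dimensional row of cages viewed by a camera that
translates parallel to the row at fixed speed and standoff, so horizontal
translation is the only motion and the projection is a pure shift: a box at
world position x (metres) appears at pixel column ``(x - camera_x) *
px_per_m``.  Each cage has its own left and right fence box and a fixed set
of chicken heads in its interior; heads are static within a cage across
frames.  Boxes partially in view are clamped to the frame; boxes fully
outside are absent, so the per-frame fence count follows the
2 → 1 → 0 → 1 → 2 cycle the counting state machine consumes.

Defaults mirror a commercial layer house inspected by a rail robot:
1280x720 frames at 30 FPS, 0.2 m/s robot speed, 40x60x40 cm cages holding
5-8 birds, and a ~50 cm camera standoff (px_per_m 1200, so a 0.6 m cage
spans 720 px and the view is ~1.07 m wide).  Cages are spaced so that at
most one cage's fence pair is ever in view at a time; see docs/methods.md
for why the spacing must be at least the view width when every cage carries
its own pair of railings.

A separate noise stage emulates detector failure modes: Bernoulli per-head
misses (occlusion), Poisson false-positive heads, Gaussian localization
jitter, and fence-dropout bursts that exercise the N-consecutive-frame
transition rule.  Geometry and noise take separate seeds so one layout can
be re-noised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .types import Detection, DetectionStream, FrameRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, kinematics and layout of a synthetic inspection pass."""

    n_cages: int = 3
    occupancy_range: tuple[int, int] = (5, 8)
    fps: float = 30.0
    robot_speed_mps: float = 0.2
    frame_width_px: int = 1280
    frame_height_px: int = 720
    px_per_m: float = 1200.0
    cage_width_m: float = 0.6
    fence_width_m: float = 0.05
    gap_between_cages_m: float = 1.2
    head_size_m: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.occupancy_range
        if lo < 1 or hi < lo:
            raise ConfigError("occupancy_range: need 1 <= min <= max")
        for name in (
            "fps", "robot_speed_mps", "px_per_m", "cage_width_m",
            "fence_width_m", "head_size_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_cages < 1:
            raise ConfigError("n_cages must be >= 1")
        if self.gap_between_cages_m < 0:
            raise ConfigError("gap_between_cages_m must be >= 0")

    @property
    def view_width_m(self) -> float:
        return self.frame_width_px / self.px_per_m

    @property
    def metres_per_frame(self) -> float:
        return self.robot_speed_mps / self.fps

    @property
    def frames_per_cage_width(self) -> float:
        """Frames the camera needs to traverse one cage width."""
        return self.cage_width_m / self.robot_speed_mps * self.fps

    def two_fence_window_m(self) -> float:
        """Length of camera travel per cage during which exactly its two
        fences are in view (may be <= 0 for inconsistent geometry)."""
        cw, fw = self.cage_width_m, self.fence_width_m
        g, v = self.gap_between_cages_m, self.view_width_m
        lo = max(-g, cw - fw - v)
        hi = min(fw, cw + g - v)
        return hi - lo


@dataclass(frozen=True)
class NoiseConfig:
    """Detector failure model applied on top of a clean stream."""

    head_miss_prob: float = 0.05
    fp_rate: float = 0.02
    jitter_px_sd: float = 2.0
    fence_dropout_prob: float = 0.01
    dropout_len_range: tuple[int, int] = (3, 8)
    confidence_model: tuple[float, float] | None = (0.9, 0.08)

    def __post_init__(self) -> None:
        for name in ("head_miss_prob", "fence_dropout_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.fp_rate < 0 or self.jitter_px_sd < 0:
            raise ConfigError("fp_rate and jitter_px_sd must be >= 0")
        lo, hi = self.dropout_len_range
        if lo < 1 or hi < lo:
            raise ConfigError("dropout_len_range: need 1 <= min <= max")

    @classmethod
    def none(cls) -> "NoiseConfig":
        """A noise model that leaves the stream untouched."""
        return cls(
            head_miss_prob=0.0,
            fp_rate=0.0,
            jitter_px_sd=0.0,
            fence_dropout_prob=0.0,
            confidence_model=None,
        )


@dataclass
class CageTruth:
    cage_id: int
    occupancy: int
    entry_frame: int  # first frame with both of this cage's fences in view
    exit_frame: int   # last such frame
    head_positions: list[tuple[float, float]] = field(default_factory=list)
    # (world x in metres, pixel y of the head-box centre)


@dataclass
class SimulationTruth:
    """Per-cage ground truth emitted alongside a synthetic stream."""

    cages: list[CageTruth]
    config: SimulationConfig

    @property
    def occupancies(self) -> list[int]:
        return [c.occupancy for c in self.cages]


def _cage_layout(cfg: SimulationConfig) -> list[dict]:
    """World-space fence and interior intervals per cage, in metres."""
    pitch = cfg.cage_width_m + cfg.gap_between_cages_m
    cages = []
    for i in range(cfg.n_cages):
        o = i * pitch
        cages.append(
            {
                "origin": o,
                "left_fence": (o, o + cfg.fence_width_m),
                "right_fence": (o + cfg.cage_width_m - cfg.fence_width_m,
                                o + cfg.cage_width_m),
                "interior": (o + cfg.fence_width_m,
                             o + cfg.cage_width_m - cfg.fence_width_m),
            }
        )
    return cages


def simulate_inspection(
    cfg: SimulationConfig,
) -> tuple[DetectionStream, SimulationTruth]:
    """Generate a clean (noise-free) inspection stream plus ground truth.

    All detections carry confidence 1.0; the output is bit-identical for
    identical configs (the geometry seed drives occupancies and head
    placement only).
    """
    if cfg.two_fence_window_m() < cfg.metres_per_frame:
        raise ConfigError(
            "geometry yields fewer than one two-fence frame per cage; "
            "increase fps, reduce robot_speed_mps, or widen "
            "gap_between_cages_m"
        )
    rng = np.random.default_rng(cfg.seed)
    layout = _cage_layout(cfg)
    H, W = cfg.frame_height_px, cfg.frame_width_px
    head_px = cfg.head_size_m * cfg.px_per_m
    margin = 0.2 * cfg.head_size_m  # keep head boxes clear of the railings

    truth_cages: list[CageTruth] = []
    for i, cage in enumerate(layout):
        occ = int(rng.integers(cfg.occupancy_range[0], cfg.occupancy_range[1] + 1))
        lo, hi = cage["interior"]
        lo += cfg.head_size_m / 2 + margin
        hi -= cfg.head_size_m / 2 + margin
        xs = rng.uniform(lo, hi, size=occ)
        ys = rng.uniform(0.3 * H, 0.7 * H, size=occ)
        truth_cages.append(
            CageTruth(
                cage_id=i + 1,
                occupancy=occ,
                entry_frame=-1,
                exit_frame=-1,
                head_positions=[(float(x), float(y)) for x, y in zip(xs, ys)],
            )
        )

    view = cfg.view_width_m
    step_m = cfg.metres_per_frame
    a0 = -view - 0.1  # stream starts with an empty view
    total_end = layout[-1]["right_fence"][1] + 0.15  # tail: ends a final cage
    n_frames = int(math.ceil((total_end - a0) / step_m)) + 1

    frames: list[FrameRecord] = []
    for t in range(n_frames):
        a = a0 + t * step_m
        dets: list[Detection] = []
        for i, cage in enumerate(layout):
            # skip cages entirely outside the view window
            if cage["origin"] > a + view or cage["right_fence"][1] < a:
                continue
            fences_here = 0
            for key in ("left_fence", "right_fence"):
                x0, x1 = cage[key]
                det = Detection(
                    "fence",
                    ((x0 - a) * cfg.px_per_m, 0.0, (x1 - a) * cfg.px_per_m, float(H)),
                ).clamped((W, H))
                if det is not None:
                    dets.append(det)
                    fences_here += 1
            if fences_here == 2:
                tc = truth_cages[i]
                if tc.entry_frame < 0:
                    tc.entry_frame = t
                tc.exit_frame = t
            for x_m, y_px in truth_cages[i].head_positions:
                det = Detection(
                    "chicken_head",
                    (
                        (x_m - cfg.head_size_m / 2 - a) * cfg.px_per_m,
                        y_px - head_px / 2,
                        (x_m + cfg.head_size_m / 2 - a) * cfg.px_per_m,
                        y_px + head_px / 2,
                    ),
                ).clamped((W, H))
                if det is not None:
                    dets.append(det)
        frames.append(
            FrameRecord(
                frame_index=t,
                timestamp_s=t / cfg.fps,
                detections=dets,
                image_size=(W, H),
            )
        )
    stream = DetectionStream(
        frames=frames,
        fps=cfg.fps,
        metadata={"simulated": True, "n_cages": cfg.n_cages, "seed": cfg.seed},
    )
    return stream, SimulationTruth(cages=truth_cages, config=cfg)


def apply_noise(
    stream: DetectionStream,
    noise: NoiseConfig,
    seed: int = 0,
) -> DetectionStream:
    """Corrupt a clean stream with the configured detector failure modes.

    Misses, jitter and false positives apply to heads; dropout bursts remove
    one fence of the visible pair for a sampled number of consecutive
    frames.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    out_frames: list[FrameRecord] = []
    burst_left = 0
    burst_side = 0
    for frame in stream:
        W, H = frame.image_size
        fences = sorted(frame.by_label("fence"), key=lambda d: d.x_center)
        heads = frame.by_label("chicken_head")

        if burst_left == 0 and noise.fence_dropout_prob > 0.0:
            if rng.random() < noise.fence_dropout_prob:
                lo, hi = noise.dropout_len_range
                burst_left = int(rng.integers(lo, hi + 1))
                burst_side = int(rng.integers(0, 2))
        if burst_left > 0:
            if fences:
                del fences[min(burst_side, len(fences) - 1)]
            burst_left -= 1

        new_heads: list[Detection] = []
        for head in heads:
            if noise.head_miss_prob > 0.0 and rng.random() < noise.head_miss_prob:
                continue
            box = head.box
            if noise.jitter_px_sd > 0.0:
                dx, dy = rng.normal(0.0, noise.jitter_px_sd, size=2)
                box = (box[0] + dx, box[1] + dy, box[2] + dx, box[3] + dy)
            det = Detection(head.label, box, head.confidence).clamped((W, H))
            if det is not None:
                new_heads.append(det)
        if noise.fp_rate > 0.0:
            size = 0.05 * 1200.0  # nominal head-box size in px
            for _ in range(int(rng.poisson(noise.fp_rate))):
                cx = rng.uniform(size / 2, W - size / 2)
                cy = rng.uniform(size / 2, H - size / 2)
                new_heads.append(
                    Detection(
                        "chicken_head",
                        (cx - size / 2, cy - size / 2, cx + size / 2, cy + size / 2),
                    )
                )

        dets = fences + new_heads
        if noise.confidence_model is not None:
            mean, sd = noise.confidence_model
            confs = np.clip(rng.normal(mean, sd, size=len(dets)), 0.0, 1.0)
            dets = [replace(d, confidence=float(c)) for d, c in zip(dets, confs)]
        out_frames.append(
            FrameRecord(
                frame_index=frame.frame_index,
                timestamp_s=frame.timestamp_s,
                detections=dets,
                image_size=frame.image_size,
            )
        )
    return DetectionStream(
        frames=out_frames, fps=stream.fps, metadata=dict(stream.metadata)
    )


def make_fig11_fixture() -> FrameRecord:
    """A single worked-example frame: two fences and 11 detected heads, of
    which exactly 3 have x-centers outside the fence span.

    The 8 in-span heads lie fully between the facing fence edges and the 3
    out-of-span heads fully outside the fence envelope, so every combination
    of span mode (outer/inner) and membership (center/full_box) keeps the
    same 8 heads.
    """
    fences = [
        Detection("fence", (100.0, 0.0, 180.0, 700.0), 0.95),
        Detection("fence", (1050.0, 0.0, 1130.0, 700.0), 0.93),
    ]
    # (x_center, y_center) of the 8 heads inside the cage
    inside = [
        (250, 300), (340, 420), (430, 260), (520, 380),
        (610, 310), (700, 450), (800, 280), (950, 360),
    ]
    # 2 heads in the left neighbour region, 1 in the right
    outside = [(45, 320), (62, 430), (1200, 340)]
    heads = [
        Detection(
            "chicken_head",
            (x - 30.0, y - 30.0, x + 30.0, y + 30.0),
            0.80 + 0.01 * (i % 10),
        )
        for i, (x, y) in enumerate(inside + outside)
    ]
    return FrameRecord(
        frame_index=0,
        timestamp_s=0.0,
        detections=fences + heads,
        image_size=(1280, 720),
    )


def simulate_noisy_inspection(
    cfg: SimulationConfig,
    noise: NoiseConfig | None = None,
    noise_seed: int | None = None,
) -> tuple[DetectionStream, SimulationTruth]:
    """Convenience wrapper: clean simulation followed by the noise stage."""
    stream, truth = simulate_inspection(cfg)
    if noise is None:
        return stream, truth
    seed = cfg.seed + 1 if noise_seed is None else noise_seed
    return apply_noise(stream, noise, seed=seed), truth
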