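"""Reading and writing detection streams in three dialects.

Dialects
--------
``jsonl`` (canonical)
    One frame per line.  An optional first line ``{"type": "metadata", ...}``
    carries ``fps``, a default ``image_size`` and free-form metadata.  Each
    frame line is ``{"frame_index": i, "timestamp_s": t, "image_size": [w, h],
    "detections": [{"label": ..., "box": [x0, y0, x1, y1],
    "confidence": c}, ...]}``.

``coco_json``
    A single COCO-style results document with ``images`` (carrying
    ``frame_index`` and ``timestamp_s``), ``annotations`` with ``bbox`` in
    ``[x, y, w, h]`` form and a ``score``, and ``categories``.

``yolo_txt_dir``
    A directory of per-frame text files ``frame_<index>.txt`` with rows
    ``class cx cy w h [confidence]`` in coordinates normalized to the image
    size.  The image size and fps are not stored in this dialect and must be
    supplied by the caller.

All readers canonicalize to pixel corner boxes, clamp boxes to the frame,
and sort frames by frame index.  Round-trips reproduce a stream to 1e-6.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import ClassMappingError, StreamParseError, StreamValidationError
from .types import CageRecord, Detection, DetectionStream, FrameRecord, LABELS

DIALECTS = ("jsonl", "coco_json", "yolo_txt_dir")

#: Default numeric ids for the yolo_txt dialect (overridable via
#: ``class_map``); COCO categories use id = index + 1.
DEFAULT_CLASS_MAP: dict[int, str] = {0: "chicken_head", 1: "fence"}


def _clamp_frame(frame: FrameRecord) -> FrameRecord:
    """Clamp all boxes to the frame, dropping boxes entirely outside it."""
    kept = []
    for det in frame.detections:
        c = det.clamped(frame.image_size)
        if c is not None:
            kept.append(c)
    frame.detections = kept
    return frame


# ---------------------------------------------------------------------------
# jsonl

def _read_jsonl(path: Path) -> DetectionStream:
    frames: list[FrameRecord] = []
    fps = 30.0
    metadata: dict[str, Any] = {}
    default_size: tuple[int, int] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(str(path), lineno, f"invalid JSON: {exc}")
            if obj.get("type") == "metadata":
                fps = float(obj.get("fps", fps))
                metadata = dict(obj.get("metadata", {}))
                if "image_size" in obj:
                    default_size = tuple(obj["image_size"])  # type: ignore[assignment]
                continue
            try:
                size = tuple(obj.get("image_size", default_size or (1280, 720)))
                dets = [
                    Detection(
                        label=d["label"],
                        box=tuple(float(v) for v in d["box"]),
                        confidence=float(d.get("confidence", 1.0)),
                    )
                    for d in obj.get("detections", [])
                ]
                frame = FrameRecord(
                    frame_index=int(obj["frame_index"]),
                    timestamp_s=float(obj["timestamp_s"]),
                    detections=dets,
                    image_size=size,  # type: ignore[arg-type]
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(str(path), lineno, f"malformed frame: {exc}")
            frames.append(_clamp_frame(frame))
    frames.sort(key=lambda f: f.frame_index)
    return DetectionStream(frames=frames, fps=fps, metadata=metadata)


def _write_jsonl(stream: DetectionStream, path: Path) -> None:
    with open(path, "w") as fh:
        header = {
            "type": "metadata",
            "fps": stream.fps,
            "metadata": stream.metadata,
        }
        fh.write(json.dumps(header) + "\n")
        for frame in stream.frames:
            obj = {
                "frame_index": frame.frame_index,
                "timestamp_s": frame.timestamp_s,
                "image_size": list(frame.image_size),
                "detections": [
                    {
                        "label": d.label,
                        "box": list(d.box),
                        "confidence": d.confidence,
                    }
                    for d in frame.detections
                ],
            }
            fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# coco_json

def _read_coco(path: Path) -> DetectionStream:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise StreamParseError(str(path), None, f"invalid JSON: {exc}")
    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    for cid, name in cat_names.items():
        if name not in LABELS:
            raise ClassMappingError(f"unknown category {name!r} (id {cid})")
    frames_by_id: dict[int, FrameRecord] = {}
    for img in doc.get("images", []):
        frames_by_id[img["id"]] = FrameRecord(
            frame_index=int(img.get("frame_index", img["id"])),
            timestamp_s=float(img.get("timestamp_s", 0.0)),
            detections=[],
            image_size=(img["width"], img["height"]),
        )
    for ann in doc.get("annotations", []):
        img_id = ann["image_id"]
        if img_id not in frames_by_id:
            raise StreamParseError(
                str(path), None, f"annotation references unknown image {img_id}"
            )
        cid = ann["category_id"]
        if cid not in cat_names:
            raise ClassMappingError(f"unknown category id {cid}")
        x, y, w, h = ann["bbox"]
        frames_by_id[img_id].detections.append(
            Detection(
                label=cat_names[cid],
                box=(float(x), float(y), float(x + w), float(y + h)),
                confidence=float(ann.get("score", 1.0)),
            )
        )
    info = doc.get("info", {})
    frames = sorted(frames_by_id.values(), key=lambda f: f.frame_index)
    return DetectionStream(
        frames=[_clamp_frame(f) for f in frames],
        fps=float(info.get("fps", 30.0)),
        metadata=dict(info.get("metadata", {})),
    )


def _write_coco(stream: DetectionStream, path: Path) -> None:
    images, annotations = [], []
    cat_ids = {name: i + 1 for i, name in enumerate(LABELS)}
    ann_id = 1
    for img_id, frame in enumerate(stream.frames, start=1):
        images.append(
            {
                "id": img_id,
                "width": frame.image_size[0],
                "height": frame.image_size[1],
                "frame_index": frame.frame_index,
                "timestamp_s": frame.timestamp_s,
            }
        )
        for det in frame.detections:
            x0, y0, x1, y1 = det.box
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_ids[det.label],
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "score": det.confidence,
                }
            )
            ann_id += 1
    doc = {
        "info": {"fps": stream.fps, "metadata": stream.metadata},
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# yolo_txt_dir

def _frame_index_of(fname: str) -> int:
    stem = Path(fname).stem
    digits = stem.split("_")[-1]
    try:
        return int(digits)
    except ValueError:
        raise StreamParseError(fname, None, "cannot parse frame index from name")


def _read_yolo_dir(
    path: Path,
    image_size: tuple[int, int],
    fps: float,
    class_map: Mapping[int, str],
) -> DetectionStream:
    w, h = image_size
    frames = []
    for fname in sorted(os.listdir(path)):
        if not fname.endswith(".txt"):
            continue
        idx = _frame_index_of(fname)
        dets = []
        fpath = path / fname
        with open(fpath) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) not in (5, 6):
                    raise StreamParseError(
                        str(fpath), lineno, f"expected 5 or 6 fields, got {len(parts)}"
                    )
                try:
                    cid = int(parts[0])
                    cx, cy, bw, bh = (float(v) for v in parts[1:5])
                    conf = float(parts[5]) if len(parts) == 6 else 1.0
                except ValueError as exc:
                    raise StreamParseError(str(fpath), lineno, f"bad number: {exc}")
                if cid not in class_map:
                    raise ClassMappingError(
                        f"{fpath}:{lineno}: unknown class id {cid}"
                    )
                dets.append(
                    Detection(
                        label=class_map[cid],
                        box=(
                            (cx - bw / 2) * w,
                            (cy - bh / 2) * h,
                            (cx + bw / 2) * w,
                            (cy + bh / 2) * h,
                        ),
                        confidence=conf,
                    )
                )
        frames.append(
            _clamp_frame(
                FrameRecord(
                    frame_index=idx,
                    timestamp_s=idx / fps,
                    detections=dets,
                    image_size=image_size,
                )
            )
        )
    frames.sort(key=lambda f: f.frame_index)
    return DetectionStream(frames=frames, fps=fps)


def _write_yolo_dir(
    stream: DetectionStream, path: Path, class_map: Mapping[int, str]
) -> None:
    inv = {name: cid for cid, name in class_map.items()}
    path.mkdir(parents=True, exist_ok=True)
    for frame in stream.frames:
        w, h = frame.image_size
        lines = []
        for det in frame.detections:
            x0, y0, x1, y1 = det.box
            # 10 decimals keep the pixel round-trip within 1e-6
            lines.append(
                f"{inv[det.label]} {(x0 + x1) / 2 / w:.10f} {(y0 + y1) / 2 / h:.10f} "
                f"{(x1 - x0) / w:.10f} {(y1 - y0) / h:.10f} {det.confidence:.10f}"
            )
        fname = path / f"frame_{frame.frame_index:06d}.txt"
        fname.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# public API

def read_stream(
    path: str | Path,
    dialect: str = "jsonl",
    *,
    image_size: tuple[int, int] | None = None,
    fps: float | None = None,
    class_map: Mapping[int, str] | None = None,
) -> DetectionStream:
    """Read a detection stream and canonicalize it.

    ``image_size`` and ``fps`` are required for the ``yolo_txt_dir`` dialect,
    which does not store them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stream path does not exist: {path}")
    if dialect == "jsonl":
        return _read_jsonl(path)
    if dialect == "coco_json":
        return _read_coco(path)
    if dialect == "yolo_txt_dir":
        if image_size is None or fps is None:
            raise StreamValidationError(
                "yolo_txt_dir requires image_size and fps"
            )
        return _read_yolo_dir(path, image_size, fps, class_map or DEFAULT_CLASS_MAP)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_stream(
    stream: DetectionStream,
    path: str | Path,
    dialect: str = "jsonl",
    *,
    class_map: Mapping[int, str] | None = None,
) -> None:
    """Write a stream so that :func:`read_stream` reproduces it to 1e-6."""
    path = Path(path)
    if dialect == "jsonl":
        _write_jsonl(stream, path)
    elif dialect == "coco_json":
        _write_coco(stream, path)
    elif dialect == "yolo_txt_dir":
        _write_yolo_dir(stream, path, class_map or DEFAULT_CLASS_MAP)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_cage_records(
    records: Sequence[CageRecord],
    path: str | Path,
    *,
    config_hash: str | None = None,
) -> None:
    """Write per-cage results as CSV, one row per cage in traversal order.

    Timestamps are serialized with millisecond (3-decimal) precision.  An
    optional provenance hash is recorded as a leading ``#`` comment line.
    """
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        writer = csv.writer(fh)
        writer.writerow(["cage_id", "max_count", "key_frame_index", "timestamp_s"])
        for rec in records:
            writer.writerow(
                [rec.cage_id, rec.max_count, rec.key_frame_index,
                 f"{rec.timestamp_s:.3f}"]
            )


def read_cage_records(path: str | Path) -> list[CageRecord]:
    """Read back a cage-record CSV written by :func:`write_cage_records`."""
    records = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#")]
    for row in rows[1:]:
        records.append(
            CageRecord(int(row[0]), int(row[1]), int(row[2]), float(row[3]))
        )
    return records
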