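"""Reading and writing detection scenes, manifests and count tables.

Detections enter the toolkit as data — either YOLO-style normalized label
text files (one per image, ``class cx cy w h [conf]``) or a COCO-style
detection JSON (``images`` / ``annotations`` / ``categories``). Per-image
feeding counts leave as a plain CSV that round-trips losslessly, and an
image manifest CSV supplies the timestamps needed for temporal aggregation.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .geometry import Box

logger = logging.getLogger(__name__)

__all__ = [
    "HEAD",
    "STANDING",
    "LYING_BELLY",
    "LYING_SIDE",
    "FEEDER",
    "LABELS",
    "POSTURES",
    "DEFAULT_CLASS_MAP",
    "Detection",
    "Scene",
    "CountRecord",
    "read_yolo_scene",
    "write_yolo_scene",
    "read_coco_scenes",
    "write_coco_scenes",
    "read_manifest",
    "write_manifest",
    "read_counts",
    "write_counts",
]

HEAD = "Head"
STANDING = "Standing"
LYING_BELLY = "LyingBelly"
LYING_SIDE = "LyingSide"
FEEDER = "Feeder"

#: The closed five-class detection vocabulary: pig heads, the three body
#: posture classes, and the fixed feeder bins.
LABELS = (HEAD, STANDING, LYING_BELLY, LYING_SIDE, FEEDER)

#: Body posture classes. Only Standing is compatible with feeding — the
#: trough is too high to eat from while lying.
POSTURES = (STANDING, LYING_BELLY, LYING_SIDE)

#: Default class-index assignment for YOLO label files; detectors trained
#: with a different ordering pass their own mapping.
DEFAULT_CLASS_MAP: dict[int, str] = {
    0: HEAD,
    1: STANDING,
    2: LYING_BELLY,
    3: LYING_SIDE,
    4: FEEDER,
}

_CANONICAL = {name.lower(): name for name in LABELS}


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, a class label and an optional confidence."""

    box: Box
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; accepted labels: {', '.join(LABELS)}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )

    @property
    def is_body(self) -> bool:
        return self.label in POSTURES


@dataclass
class Scene:
    """All detections for one image, plus image size and optional timestamp."""

    image_id: str
    width: float
    height: float
    timestamp: Optional[datetime] = None
    detections: list[Detection] = field(default_factory=list)

    def heads(self) -> list[Detection]:
        return [d for d in self.detections if d.label == HEAD]

    def bodies(self) -> list[Detection]:
        return [d for d in self.detections if d.label in POSTURES]

    def feeders(self) -> list[Detection]:
        return [d for d in self.detections if d.label == FEEDER]


@dataclass(frozen=True)
class CountRecord:
    """Per-image feeding count: predicted, and actual when ground truth exists."""

    image_id: str
    timestamp: Optional[datetime] = None
    predicted: int = 0
    actual: Optional[int] = None

    def __post_init__(self) -> None:
        if self.predicted < 0:
            raise ValueError(f"predicted count must be ≥ 0, got {self.predicted}")
        if self.actual is not None and self.actual < 0:
            raise ValueError(f"actual count must be ≥ 0, got {self.actual}")


def _clamp_box(box: Box, width: float, height: float, context: str) -> Box:
    """Clamp a box to image bounds, warning when anything was cut.

    Detectors routinely emit boxes that spill a few pixels past the frame;
    rejecting them would discard real pigs, so clamping is the lossy-but-sane
    policy.
    """
    clamped = Box(
        min(max(box.x_min, 0.0), width),
        min(max(box.y_min, 0.0), height),
        min(max(box.x_max, 0.0), width),
        min(max(box.y_max, 0.0), height),
    )
    if clamped != box:
        logger.warning("%s: box %s clamped to image bounds %gx%g", context, box, width, height)
    return clamped


def read_yolo_scene(
    label_file: str | Path,
    width: float,
    height: float,
    class_map: Mapping[int, str] | None = None,
    image_id: str | None = None,
    timestamp: Optional[datetime] = None,
) -> Scene:
    """Read one YOLO label text file into a :class:`Scene`.

    Each non-empty line is ``class_idx cx cy w h [conf]`` with coordinates
    normalized to [0, 1]; boxes are denormalized to pixels using the given
    image size. Unknown class indices and malformed lines are errors naming
    the offending line.
    """
    label_file = Path(label_file)
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    if image_id is None:
        image_id = label_file.stem
    detections: list[Detection] = []
    for lineno, raw in enumerate(label_file.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise ValueError(
                f"{label_file}:{lineno}: expected 'class cx cy w h [conf]', got {raw!r}"
            )
        try:
            cls_idx = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else 1.0
        except ValueError as exc:
            raise ValueError(f"{label_file}:{lineno}: unparseable field ({exc})") from exc
        if cls_idx not in class_map:
            raise ValueError(
                f"{label_file}:{lineno}: class index {cls_idx} not in class map "
                f"{sorted(class_map)}"
            )
        if w < 0 or h < 0:
            raise ValueError(
                f"{label_file}:{lineno}: negative box extent (w={w}, h={h})"
            )
        box = Box(
            (cx - w / 2.0) * width,
            (cy - h / 2.0) * height,
            (cx + w / 2.0) * width,
            (cy + h / 2.0) * height,
        )
        box = _clamp_box(box, width, height, f"{label_file}:{lineno}")
        detections.append(Detection(box=box, label=class_map[cls_idx], confidence=conf))
    return Scene(
        image_id=image_id,
        width=width,
        height=height,
        timestamp=timestamp,
        detections=detections,
    )


def write_yolo_scene(
    scene: Scene,
    label_file: str | Path,
    class_map: Mapping[int, str] | None = None,
) -> None:
    """Write a scene as a YOLO label file (inverse of :func:`read_yolo_scene`)."""
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    index_of = {name: idx for idx, name in class_map.items()}
    lines = []
    for det in scene.detections:
        b = det.box
        cx = (b.x_min + b.x_max) / 2.0 / scene.width
        cy = (b.y_min + b.y_max) / 2.0 / scene.height
        w = b.width / scene.width
        h = b.height / scene.height
        lines.append(
            f"{index_of[det.label]} {cx:.8f} {cy:.8f} {w:.8f} {h:.8f} {det.confidence:.6f}"
        )
    Path(label_file).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_coco_scenes(json_file: str | Path) -> list[Scene]:
    """Read a COCO-style detection JSON into one :class:`Scene` per image.

    ``bbox`` entries are ``[x, y, w, h]`` and are converted to corner form;
    category names are matched case-insensitively against the five-class
    vocabulary.
    """
    json_file = Path(json_file)
    data = json.loads(json_file.read_text())
    categories: dict[int, str] = {}
    for cat in data.get("categories", []):
        name = str(cat["name"])
        canonical = _CANONICAL.get(name.lower())
        if canonical is None:
            raise ValueError(
                f"{json_file}: category {name!r} outside the vocabulary; "
                f"accepted names: {', '.join(LABELS)}"
            )
        categories[int(cat["id"])] = canonical

    scenes: dict[object, Scene] = {}
    for img in data.get("images", []):
        ts = img.get("timestamp")
        scenes[img["id"]] = Scene(
            image_id=str(img.get("file_name", img["id"])),
            width=float(img["width"]),
            height=float(img["height"]),
            timestamp=datetime.fromisoformat(ts) if ts else None,
        )
    for ann in data.get("annotations", []):
        image_id = ann["image_id"]
        if image_id not in scenes:
            raise ValueError(
                f"{json_file}: annotation {ann.get('id', '?')} references missing "
                f"image_id {image_id}"
            )
        cat_id = int(ann["category_id"])
        if cat_id not in categories:
            raise ValueError(
                f"{json_file}: annotation {ann.get('id', '?')} references unknown "
                f"category_id {cat_id}"
            )
        x, y, w, h = (float(v) for v in ann["bbox"])
        if w < 0 or h < 0:
            raise ValueError(
                f"{json_file}: annotation {ann.get('id', '?')} has negative bbox "
                f"extent (w={w}, h={h})"
            )
        scene = scenes[image_id]
        box = _clamp_box(
            Box(x, y, x + w, y + h), scene.width, scene.height,
            f"{json_file}:annotation {ann.get('id', '?')}",
        )
        scene.detections.append(
            Detection(box=box, label=categories[cat_id], confidence=float(ann.get("score", 1.0)))
        )
    return list(scenes.values())


def write_coco_scenes(scenes: Sequence[Scene], json_file: str | Path) -> None:
    """Write scenes as a COCO-style detection JSON (inverse of the reader)."""
    cat_id = {name: i + 1 for i, name in enumerate(LABELS)}
    images = []
    annotations = []
    ann_id = 1
    for img_idx, scene in enumerate(scenes, start=1):
        entry: dict[str, object] = {
            "id": img_idx,
            "file_name": scene.image_id,
            "width": scene.width,
            "height": scene.height,
        }
        if scene.timestamp is not None:
            entry["timestamp"] = scene.timestamp.isoformat()
        images.append(entry)
        for det in scene.detections:
            b = det.box
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": cat_id[det.label],
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "score": det.confidence,
                }
            )
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": name} for name, i in cat_id.items()],
    }
    Path(json_file).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_manifest(csv_file: str | Path) -> dict[str, datetime]:
    """Read an ``image_id,timestamp`` CSV into a mapping; duplicates are errors."""
    csv_file = Path(csv_file)
    mapping: dict[str, datetime] = {}
    with csv_file.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "image_id" not in reader.fieldnames or "timestamp" not in reader.fieldnames:
            raise ValueError(
                f"{csv_file}: expected header with 'image_id' and 'timestamp' columns, "
                f"got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            image_id = row["image_id"]
            if image_id in mapping:
                raise ValueError(f"{csv_file}:{rownum}: duplicate image_id {image_id!r}")
            try:
                mapping[image_id] = datetime.fromisoformat(row["timestamp"])
            except ValueError as exc:
                raise ValueError(
                    f"{csv_file}:{rownum}: unparseable timestamp {row['timestamp']!r}"
                ) from exc
    return mapping


def write_manifest(mapping: Mapping[str, datetime], csv_file: str | Path) -> None:
    with Path(csv_file).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "timestamp"])
        for image_id, ts in mapping.items():
            writer.writerow([image_id, ts.isoformat()])


def write_counts(records: Iterable[CountRecord], csv_file: str | Path) -> None:
    """Write count records as CSV; optional fields are written empty."""
    with Path(csv_file).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "timestamp", "predicted", "actual"])
        for rec in records:
            writer.writerow(
                [
                    rec.image_id,
                    rec.timestamp.isoformat() if rec.timestamp is not None else "",
                    rec.predicted,
                    rec.actual if rec.actual is not None else "",
                ]
            )


def read_counts(csv_file: str | Path) -> list[CountRecord]:
    """Read a counts CSV written by :func:`write_counts`."""
    csv_file = Path(csv_file)
    records: list[CountRecord] = []
    with csv_file.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image_id", "predicted"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{csv_file}: expected at least columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            ts_raw = (row.get("timestamp") or "").strip()
            actual_raw = (row.get("actual") or "").strip()
            try:
                records.append(
                    CountRecord(
                        image_id=row["image_id"],
                        timestamp=datetime.fromisoformat(ts_raw) if ts_raw else None,
                        predicted=int(row["predicted"]),
                        actual=int(actual_raw) if actual_raw else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{csv_file}:{rownum}: {exc}") from exc
    return records
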