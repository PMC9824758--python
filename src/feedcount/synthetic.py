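"""Seeded generator of top-view barn scenes with known ground truth.

Real barn footage gives detections, never certainty about which pigs were
feeding. This module builds detection-level scenes (no images) whose
ground-truth feeding count is known by construction, so every pipeline
stage and the SADR metric can be exercised without a dataset.

What a generated scene emulates:

* a fixed top-view arena (default 640×640) with fixed feeder boxes
  (default two, mirroring a two-trough barn);
* pigs as head+body box pairs — the body roughly 2:1 with the head box at
  one end of its major axis, so the farthest-center mapping rule is correct
  by construction, and the body covers most of the head (coverage ≥ 0.5);
* feeding pigs: Standing, head overlapping a feeder strictly above any
  reasonable IoU gate;
* the classic false-positive trap: non-feeding pigs *lying* directly
  against a feeder, indistinguishable from feeders by proximity alone;
* detector imperfections: head dropout (occlusion) and box-corner jitter.

Pigs never overlap one another (rejection-sampled placement), so in a
noise-free scene the head→body mapping is unambiguous and the pipeline
recovers the true count exactly — the end-to-end correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import Box, intersection_area
from .io import (
    FEEDER,
    HEAD,
    LYING_BELLY,
    LYING_SIDE,
    POSTURES,
    STANDING,
    CountRecord,
    Detection,
    Scene,
    write_coco_scenes,
    write_counts,
    write_manifest,
    write_yolo_scene,
)

__all__ = [
    "SimConfig",
    "SimulationError",
    "generate_scene",
    "generate_batch",
    "generate_timeseries",
    "make_interleaved_scene",
    "write_dataset",
]


class SimulationError(RuntimeError):
    """Raised when a scene cannot be laid out (arena too crowded)."""


@dataclass(frozen=True)
class SimConfig:
    """Barn and detector parameters for scene generation.

    Defaults describe the emulated barn: a 640×640 top view with two fixed
    feeder bins, a pen of 12 pigs, a quarter of them feeding at a random
    hour, and — among the non-feeding, non-standing pigs — a 50% chance of
    lying directly against a feeder (the proximity-only false positive).
    """

    image_width: float = 640.0
    image_height: float = 640.0
    n_pigs: int = 12
    n_feeders: int = 2
    feeder_boxes: Optional[tuple[Box, ...]] = None
    p_feeding: float = 0.25
    posture_probs: Mapping[str, float] = field(
        default_factory=lambda: {STANDING: 0.30, LYING_BELLY: 0.35, LYING_SIDE: 0.35}
    )
    p_lie_near_feeder: float = 0.5
    head_dropout_prob: float = 0.0
    jitter_px: float = 0.0
    seed: Optional[int] = None
    max_retries: int = 500

    def __post_init__(self) -> None:
        if self.n_pigs < 0:
            raise ValueError(f"n_pigs must be ≥ 0, got {self.n_pigs}")
        if self.n_feeders < 0:
            raise ValueError(f"n_feeders must be ≥ 0, got {self.n_feeders}")
        for name in ("p_feeding", "p_lie_near_feeder", "head_dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.jitter_px < 0:
            raise ValueError(f"jitter_px must be ≥ 0, got {self.jitter_px}")
        unknown = set(self.posture_probs) - set(POSTURES)
        if unknown:
            raise ValueError(f"posture_probs has unknown postures {sorted(unknown)}")
        total = sum(self.posture_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posture_probs must sum to 1, got {total}")

    def resolved_feeders(self) -> tuple[Box, ...]:
        """Configured feeder boxes, or auto-placed ones along the mid line."""
        if self.feeder_boxes is not None:
            return tuple(self.feeder_boxes)
        W, H = self.image_width, self.image_height
        fw, fh = 0.18 * W, 0.22 * H
        boxes = []
        for i in range(self.n_feeders):
            cx = (i + 1) / (self.n_feeders + 1) * W
            boxes.append(Box(cx - fw / 2, H / 2 - fh / 2, cx + fw / 2, H / 2 + fh / 2))
        return tuple(boxes)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config fields {sorted(unknown)}; accepted: {sorted(known)}"
            )
        if raw.get("feeder_boxes") is not None:
            raw["feeder_boxes"] = tuple(Box(*map(float, b)) for b in raw["feeder_boxes"])
        return cls(**raw)


# Pig geometry relative to its body's short side: bodies are ~2:1 rectangles,
# the head box is ~0.65 of the short side and sits at one major-axis end with
# 60% of its length inside the body (coverage 0.6 ≥ 0.5 by construction).
_HEAD_FRACTION = 0.65
_HEAD_INSIDE = 0.6


def _expand(b: Box, m: float) -> Box:
    return Box(b.x_min - m, b.y_min - m, b.x_max + m, b.y_max + m)


def _collides(boxes: Sequence[Box], placed: Sequence[Box], margin: float) -> bool:
    for b in boxes:
        for p in placed:
            if intersection_area(b, _expand(p, margin)) > 0.0:
                return True
    return False


def _in_bounds(boxes: Sequence[Box], W: float, H: float) -> bool:
    return all(
        b.x_min >= 0 and b.y_min >= 0 and b.x_max <= W and b.y_max <= H for b in boxes
    )


def _pig_at_feeder(
    feeder: Box, side: int, u: float, d: float, bh: float, bl: float, hs: float
) -> tuple[Box, Box]:
    """Head and body boxes for a pig with its snout ``d`` pixels into a feeder.

    ``side`` 0–3 = approach from left/right/above/below; ``u`` positions the
    pig along the feeder edge.
    """
    if side in (0, 1):  # horizontal pig
        cy = feeder.y_min + u * (feeder.y_max - feeder.y_min)
        if side == 0:  # pig left of feeder, facing right
            head = Box(feeder.x_min - (hs - d), cy - hs / 2, feeder.x_min + d, cy + hs / 2)
            bx_max = head.x_min + _HEAD_INSIDE * hs
            body = Box(bx_max - bl, cy - bh / 2, bx_max, cy + bh / 2)
        else:  # pig right of feeder, facing left
            head = Box(feeder.x_max - d, cy - hs / 2, feeder.x_max + (hs - d), cy + hs / 2)
            bx_min = head.x_max - _HEAD_INSIDE * hs
            body = Box(bx_min, cy - bh / 2, bx_min + bl, cy + bh / 2)
    else:  # vertical pig
        cx = feeder.x_min + u * (feeder.x_max - feeder.x_min)
        if side == 2:  # pig above feeder, facing down
            head = Box(cx - hs / 2, feeder.y_min - (hs - d), cx + hs / 2, feeder.y_min + d)
            by_max = head.y_min + _HEAD_INSIDE * hs
            body = Box(cx - bh / 2, by_max - bl, cx + bh / 2, by_max)
        else:  # pig below feeder, facing up
            head = Box(cx - hs / 2, feeder.y_max - d, cx + hs / 2, feeder.y_max + (hs - d))
            by_min = head.y_max - _HEAD_INSIDE * hs
            body = Box(cx - bh / 2, by_min, cx + bh / 2, by_min + bl)
    return head, body


def _pig_away(
    rng: np.random.Generator, W: float, H: float, bh: float, bl: float, hs: float
) -> tuple[Box, Box]:
    """Head and body boxes for a pig placed at a random free spot."""
    horizontal = rng.integers(2) == 0
    flip = rng.integers(2) == 0
    if horizontal:
        bx = rng.uniform(hs, W - bl - hs)
        by = rng.uniform(hs, H - bh - hs)
        body = Box(bx, by, bx + bl, by + bh)
        cy = by + bh / 2
        if flip:
            head = Box(body.x_max - _HEAD_INSIDE * hs, cy - hs / 2,
                       body.x_max + (1 - _HEAD_INSIDE) * hs, cy + hs / 2)
        else:
            head = Box(body.x_min - (1 - _HEAD_INSIDE) * hs, cy - hs / 2,
                       body.x_min + _HEAD_INSIDE * hs, cy + hs / 2)
    else:
        bx = rng.uniform(hs, W - bh - hs)
        by = rng.uniform(hs, H - bl - hs)
        body = Box(bx, by, bx + bh, by + bl)
        cx = bx + bh / 2
        if flip:
            head = Box(cx - hs / 2, body.y_max - _HEAD_INSIDE * hs,
                       cx + hs / 2, body.y_max + (1 - _HEAD_INSIDE) * hs)
        else:
            head = Box(cx - hs / 2, body.y_min - (1 - _HEAD_INSIDE) * hs,
                       cx + hs / 2, body.y_min + _HEAD_INSIDE * hs)
    return head, body


def _jitter_box(box: Box, j: float, rng: np.random.Generator, W: float, H: float) -> Box:
    dx0, dy0, dx1, dy1 = rng.uniform(-j, j, size=4)
    x0, x1 = sorted((box.x_min + dx0, box.x_max + dx1))
    y0, y1 = sorted((box.y_min + dy0, box.y_max + dy1))
    return Box(
        min(max(x0, 0.0), W), min(max(y0, 0.0), H),
        min(max(x1, 0.0), W), min(max(y1, 0.0), H),
    )


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def generate_scene(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    image_id: str = "scene",
    timestamp: Optional[datetime] = None,
) -> tuple[Scene, CountRecord]:
    """Generate one scene and its ground-truth count record.

    The record carries ``actual`` = number of feeding pigs placed; its
    ``predicted`` field holds the same value so that ground-truth files
    aggregate through the same code paths as predictions.

    Raises :class:`SimulationError` when a pig cannot be placed without
    overlap after ``config.max_retries`` attempts. Feeding pigs claim
    trough slots before trap pigs do; a trap pig that finds the trough
    fully occupied lies down elsewhere instead (as a crowded pen would
    look), so only feeding pigs can make a scene infeasible.
    """
    rng = _rng(rng if rng is not None else config.seed)
    W, H = config.image_width, config.image_height
    feeders = config.resolved_feeders()

    postures = list(config.posture_probs)
    probs = np.array([config.posture_probs[p] for p in postures])

    # pass 1: per-pig status draws (feeding, posture, trap, dropout)
    pigs: list[dict] = []
    for _ in range(config.n_pigs):
        feeding = rng.random() < config.p_feeding
        posture_draw = postures[int(rng.choice(len(postures), p=probs))]
        trap_draw = rng.random() < config.p_lie_near_feeder
        dropout = rng.random() < config.head_dropout_prob
        if feeding:
            if not feeders:
                raise SimulationError(
                    "p_feeding > 0 requires at least one feeder in the scene"
                )
            posture, at_feeder = STANDING, True
        else:
            posture = posture_draw
            at_feeder = posture != STANDING and trap_draw and bool(feeders)
        pigs.append(
            dict(feeding=feeding, posture=posture, at_feeder=at_feeder, dropout=dropout)
        )

    def try_place(at_feeder: bool, placed: list[Box]) -> Optional[tuple[Box, Box]]:
        for _ in range(config.max_retries):
            # body size re-drawn per attempt: a tight slot at a crowded
            # feeder may admit a smaller pen-mate
            bh = rng.uniform(38.0, 50.0)
            bl = rng.uniform(1.9, 2.2) * bh
            hs = _HEAD_FRACTION * bh
            if at_feeder:
                f = feeders[int(rng.integers(len(feeders)))]
                side = int(rng.integers(4))
                u = rng.uniform(0.12, 0.88)
                d = rng.uniform(0.45, 0.75) * hs
                cand_head, cand_body = _pig_at_feeder(f, side, u, d, bh, bl, hs)
                # the head may touch its feeder; no other feeder or pig may be hit
                other_feeders = [fb for fb in feeders if fb != f]
                feeder_clash = _collides([cand_head, cand_body], other_feeders, 4.0)
            else:
                cand_head, cand_body = _pig_away(rng, W, H, bh, bl, hs)
                feeder_clash = _collides([cand_head, cand_body], feeders, 8.0)
            if (
                _in_bounds([cand_head, cand_body], W, H)
                and not feeder_clash
                and not _collides([cand_head, cand_body], placed, 2.0)
            ):
                return cand_head, cand_body
        return None

    # pass 2: feeding pigs first, then traps (with away fallback), then the rest
    placed: list[Box] = []
    order = sorted(
        range(config.n_pigs),
        key=lambda k: 0 if pigs[k]["feeding"] else (1 if pigs[k]["at_feeder"] else 2),
    )
    for k in order:
        pig = pigs[k]
        slot = try_place(pig["at_feeder"], placed)
        if slot is None and pig["at_feeder"] and not pig["feeding"]:
            slot = try_place(False, placed)  # trough full: lie down elsewhere
        if slot is None:
            raise SimulationError(
                f"could not place pig {k + 1}/{config.n_pigs} after "
                f"{config.max_retries} attempts; arena too crowded "
                f"({W:g}×{H:g}, {len(feeders)} feeders)"
            )
        pig["head"], pig["body"] = slot
        placed.extend(slot)

    detections: list[Detection] = [Detection(box=f, label=FEEDER) for f in feeders]
    n_feeding = 0
    for pig in pigs:
        head, body = pig["head"], pig["body"]
        if pig["feeding"]:
            n_feeding += 1
        if config.jitter_px > 0:
            head = _jitter_box(head, config.jitter_px, rng, W, H)
            body = _jitter_box(body, config.jitter_px, rng, W, H)
        detections.append(Detection(box=body, label=pig["posture"]))
        if not pig["dropout"]:
            detections.append(Detection(box=head, label=HEAD))

    scene = Scene(
        image_id=image_id, width=W, height=H, timestamp=timestamp, detections=detections
    )
    record = CountRecord(
        image_id=image_id, timestamp=timestamp, predicted=n_feeding, actual=n_feeding
    )
    return scene, record


def generate_batch(
    config: SimConfig, n_scenes: int, seed: int | None = None
) -> tuple[list[Scene], list[CountRecord]]:
    """Generate ``n_scenes`` independent scenes from one seeded stream."""
    rng = _rng(seed if seed is not None else config.seed)
    scenes, records = [], []
    for i in range(n_scenes):
        s, r = generate_scene(config, rng, image_id=f"scene{i:05d}")
        scenes.append(s)
        records.append(r)
    return scenes, records


def generate_timeseries(
    config: SimConfig,
    schedule: Mapping[int, float] | Sequence[float],
    n_days: int,
    seed: int | None = None,
    start_date: date = date(2022, 3, 1),
) -> tuple[list[Scene], list[CountRecord]]:
    """One scene per hour per day, feeding probability driven by ``schedule``.

    ``schedule`` maps each hour 0–23 to that hour's ``p_feeding`` (a dict
    covering all 24 hours, or a sequence of 24 values) — e.g. a bimodal
    profile with morning and afternoon mealtime peaks.
    """
    if not isinstance(schedule, Mapping):
        schedule = {h: p for h, p in enumerate(schedule)}
    missing = set(range(24)) - set(schedule)
    if missing:
        raise ValueError(f"schedule must cover all 24 hours; missing {sorted(missing)}")
    rng = _rng(seed if seed is not None else config.seed)
    scenes, records = [], []
    for day in range(n_days):
        for hour in range(24):
            ts = datetime.combine(start_date, datetime.min.time()) + timedelta(
                days=day, hours=hour
            )
            cfg = replace(config, p_feeding=float(schedule[hour]))
            s, r = generate_scene(
                cfg, rng, image_id=f"day{day:03d}_hour{hour:02d}", timestamp=ts
            )
            scenes.append(s)
            records.append(r)
    return scenes, records


def make_interleaved_scene(n_pigs: int = 2) -> tuple[Scene, list[tuple[int, int]]]:
    """Deterministic scene of adjacent, interleaved pigs for mapping tests.

    Pigs are laid out in a staggered chain so that each head overlaps its
    own body (at the far end of the body's major axis) *and* the flank of
    the next pig's body (close to that body's center) — the configuration
    where proximity-only association fails and the farthest-center rule is
    needed. Returns the scene and the true (head index, body index)
    assignment, both indexed in emission order.
    """
    if not 1 <= n_pigs <= 8:
        raise ValueError(f"n_pigs must be in [1, 8], got {n_pigs}")
    detections: list[Detection] = []
    truth = []
    for k in range(n_pigs):
        ox, oy = 60.0 * k, 40.0 * k
        body = Box(ox, oy, ox + 110.0, oy + 50.0)
        head = Box(ox + 88.0, oy + 8.0, ox + 130.0, oy + 42.0)
        detections.append(Detection(box=body, label=STANDING))
        detections.append(Detection(box=head, label=HEAD))
        truth.append((k, k))
    extent = 60.0 * (n_pigs - 1) + 130.0, 40.0 * (n_pigs - 1) + 50.0
    scene = Scene(
        image_id=f"interleaved{n_pigs}",
        width=max(640.0, extent[0]),
        height=max(640.0, extent[1]),
        detections=detections,
    )
    return scene, truth


def write_dataset(
    scenes: Sequence[Scene],
    records: Sequence[CountRecord],
    out_dir: str | Path,
) -> None:
    """Write scenes and truth in every format the pipeline consumes.

    Produces ``labels/<image_id>.txt`` (YOLO, one per scene),
    ``scenes.json`` (COCO), ``manifest.csv`` (for timestamped scenes) and
    ``truth.csv``. Output bytes are a pure function of the inputs, so a
    fixed seed reproduces the tree exactly.
    """
    out_dir = Path(out_dir)
    labels = out_dir / "labels"
    labels.mkdir(parents=True, exist_ok=True)
    for scene in scenes:
        write_yolo_scene(scene, labels / f"{scene.image_id}.txt")
    write_coco_scenes(scenes, out_dir / "scenes.json")
    manifest = {s.image_id: s.timestamp for s in scenes if s.timestamp is not None}
    if manifest:
        write_manifest(manifest, out_dir / "manifest.csv")
    write_counts(records, out_dir / "truth.csv")
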