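"""The feeding-pig counting pipeline.

Counting proceeds in four stages over the detections of one image:

1. **Candidate selection** — keep the pig heads whose IoU with any feeder
   box exceeds a gate threshold; everything else is too far from the trough
   to be feeding.
2. **Head–body mapping** — associate each candidate head with one body
   detection. Pigs crowd at the trough, so a head often overlaps several
   bodies; because a pig's head sits at the far end of its body's major
   axis, the overlapping body whose *center is farthest* from the head is
   its own. The assignment is greedy and one-to-one: a consumed body cannot
   be claimed by a second head.
3. **Body-only fallback** (optional) — a pig whose head is occluded still
   has a body near the trough; unconsumed bodies overlapping a feeder can
   be appended as headless candidates.
4. **Posture filtration** — pigs eat standing on four legs (the trough is
   too high otherwise), so only pairs whose body posture equals the feeding
   posture are counted. Disabling the gate (``feeding_posture=None``)
   recovers the distance-estimation-only baseline that over-counts pigs
   lying idly beside the trough.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .geometry import center, coverage_ratio, intersection_area, iou
from .io import STANDING, CountRecord, Detection, Scene

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PigPair",
    "select_candidate_heads",
    "map_heads_to_bodies",
    "attach_body_only_candidates",
    "filter_by_posture",
    "count_feeding_pigs",
    "count_scenes",
]

_MAPPING_DIRECTIONS = ("head_to_body", "body_to_head")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds and switches of the counting pipeline.

    Parameters
    ----------
    feeder_iou_threshold
        Candidate gate: a head is kept when its IoU with some feeder is
        *strictly* greater than this. The default 0.01 admits any genuine
        overlap with the trough.
    head_coverage_threshold
        Pairs whose head∩body / head-area falls below this are flagged as
        low-coverage (occluded or implausible head) but retained.
    allow_body_only_candidates
        Append headless pairs for unconsumed bodies overlapping a feeder —
        the occluded-head fallback. Off by default.
    feeding_posture
        Body posture counted as feeding (``"Standing"``). ``None`` accepts
        every posture, i.e. the distance-estimation-only baseline.
    mapping_direction
        ``"head_to_body"`` iterates heads and picks the farthest overlapping
        body (the default); ``"body_to_head"`` iterates bodies and picks the
        farthest overlapping head.
    """

    feeder_iou_threshold: float = 0.01
    head_coverage_threshold: float = 0.5
    allow_body_only_candidates: bool = False
    feeding_posture: Optional[str] = STANDING
    mapping_direction: str = "head_to_body"

    def __post_init__(self) -> None:
        for name in ("feeder_iou_threshold", "head_coverage_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.mapping_direction not in _MAPPING_DIRECTIONS:
            raise ValueError(
                f"mapping_direction must be one of {_MAPPING_DIRECTIONS}, "
                f"got {self.mapping_direction!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML/JSON mapping of field names to values."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config fields {sorted(unknown)}; "
                f"accepted: {sorted(known)}"
            )
        return cls(**raw)


@dataclass(frozen=True)
class PigPair:
    """A mapped (head, body) pair; ``head`` is absent for body-only candidates."""

    body: Detection
    head: Optional[Detection] = None
    low_coverage: bool = False

    def __post_init__(self) -> None:
        if not self.body.is_body:
            raise ValueError(
                f"PigPair body must carry a posture label, got {self.body.label!r}"
            )
        if self.head is not None and self.head.label != "Head":
            raise ValueError(f"PigPair head must be a Head detection, got {self.head.label!r}")

    @property
    def posture(self) -> str:
        return self.body.label


def select_candidate_heads(scene: Scene, config: PipelineConfig) -> list[Detection]:
    """Heads whose IoU with some feeder strictly exceeds the gate threshold.

    Input order is preserved. A scene with no feeder detections yields no
    candidates.
    """
    feeders = scene.feeders()
    if not feeders:
        return []
    selected = []
    for head in scene.heads():
        best = max(iou(head.box, f.box) for f in feeders)
        if best > config.feeder_iou_threshold:
            selected.append(head)
    return selected


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def map_heads_to_bodies(
    heads: Sequence[Detection],
    bodies: Sequence[Detection],
    config: PipelineConfig | None = None,
) -> list[PigPair]:
    """Greedy one-to-one association of heads with bodies.

    For each head (processed in descending confidence, ties by input order),
    the bodies with positive overlap are collected and the one whose center
    is farthest from the head's center is assigned and removed from the
    pool. A head's own body extends away from it along the body's major
    axis, so among overlapping bodies the farthest center is the right one;
    an interloping neighbour's body overlaps the head near its flank, close
    to its own center. Heads with no overlapping unconsumed body yield no
    pair. Distance ties break toward the lower body input index.

    With ``mapping_direction="body_to_head"`` the roles are swapped: each
    body claims the farthest overlapping head.
    """
    if config is None:
        config = PipelineConfig()
    if config.mapping_direction == "body_to_head":
        return _map_body_to_head(heads, bodies, config)

    order = sorted(range(len(heads)), key=lambda i: (-heads[i].confidence, i))
    pool: list[Optional[Detection]] = list(bodies)
    pairs_by_head: dict[int, PigPair] = {}
    for i in order:
        head = heads[i]
        hc = center(head.box)
        best_j = -1
        best_d = -1.0
        for j, body in enumerate(pool):
            if body is None:
                continue
            if intersection_area(head.box, body.box) <= 0.0:
                continue
            d = _dist(hc, center(body.box))
            if d > best_d:
                best_d, best_j = d, j
        if best_j < 0:
            logger.debug("head %d: no overlapping body available, left unpaired", i)
            continue
        body = pool[best_j]
        assert body is not None
        pool[best_j] = None
        low = coverage_ratio(head.box, body.box) < config.head_coverage_threshold
        pairs_by_head[i] = PigPair(body=body, head=head, low_coverage=low)
    # report in head input order regardless of the confidence-sorted pass
    return [pairs_by_head[i] for i in sorted(pairs_by_head)]


def _map_body_to_head(
    heads: Sequence[Detection],
    bodies: Sequence[Detection],
    config: PipelineConfig,
) -> list[PigPair]:
    pool: list[Optional[Detection]] = list(heads)
    pairs: list[PigPair] = []
    order = sorted(range(len(bodies)), key=lambda j: (-bodies[j].confidence, j))
    for j in order:
        body = bodies[j]
        bc = center(body.box)
        best_i = -1
        best_d = -1.0
        for i, head in enumerate(pool):
            if head is None:
                continue
            if intersection_area(head.box, body.box) <= 0.0:
                continue
            d = _dist(bc, center(head.box))
            if d > best_d:
                best_d, best_i = d, i
        if best_i < 0:
            continue
        head = pool[best_i]
        assert head is not None
        pool[best_i] = None
        low = coverage_ratio(head.box, body.box) < config.head_coverage_threshold
        pairs.append(PigPair(body=body, head=head, low_coverage=low))
    return pairs


def attach_body_only_candidates(
    pairs: Sequence[PigPair],
    bodies: Sequence[Detection],
    scene: Scene,
    config: PipelineConfig,
) -> list[PigPair]:
    """Append headless pairs for unconsumed bodies overlapping a feeder.

    Covers the occluded-head case: the pig's head is hidden by a pen-mate,
    but its body is demonstrably at the trough. No-op unless
    ``allow_body_only_candidates`` is set.
    """
    result = list(pairs)
    if not config.allow_body_only_candidates:
        return result
    feeders = scene.feeders()
    if not feeders:
        return result
    consumed = {id(p.body) for p in pairs}
    for body in bodies:
        if id(body) in consumed:
            continue
        if max(iou(body.box, f.box) for f in feeders) > config.feeder_iou_threshold:
            result.append(PigPair(body=body, head=None))
    return result


def filter_by_posture(pairs: Sequence[PigPair], config: PipelineConfig) -> int:
    """Number of pairs whose body posture is the feeding posture.

    ``feeding_posture=None`` counts every pair — the behaviour of pipelines
    that gate on trough distance alone.
    """
    if config.feeding_posture is None:
        return len(pairs)
    return sum(1 for p in pairs if p.posture == config.feeding_posture)


def count_feeding_pigs(scene: Scene, config: PipelineConfig | None = None) -> CountRecord:
    """Run the full pipeline on one scene and return its predicted count."""
    if config is None:
        config = PipelineConfig()
    candidates = select_candidate_heads(scene, config)
    bodies = scene.bodies()
    pairs = map_heads_to_bodies(candidates, bodies, config)
    pairs = attach_body_only_candidates(pairs, bodies, scene, config)
    predicted = filter_by_posture(pairs, config)
    logger.debug(
        "%s: %d candidate heads, %d pairs, predicted %d",
        scene.image_id, len(candidates), len(pairs), predicted,
    )
    return CountRecord(
        image_id=scene.image_id, timestamp=scene.timestamp, predicted=predicted
    )


def count_scenes(
    scenes: Sequence[Scene], config: PipelineConfig | None = None
) -> list[CountRecord]:
    """Convenience: :func:`count_feeding_pigs` over a batch of scenes."""
    return [count_feeding_pigs(s, config) for s in scenes]
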