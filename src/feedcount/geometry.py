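"""Axis-aligned box primitives.

Every stage of the feeding-pig pipeline reduces to a handful of overlap
computations between axis-aligned detection boxes: intersection area,
intersection-over-union (the head-to-feeder proximity gate), and the
head-coverage ratio (head∩body normalised by head area, which is
size-invariant across pigs). Boxes live in real-valued pixel coordinates
with the origin at the image top-left and y increasing downward, the
convention shared by the YOLO and COCO detection formats.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Box",
    "intersection_area",
    "iou",
    "coverage_ratio",
    "center",
    "major_axis_endpoints",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle ``[x_min, x_max] × [y_min, y_max]`` in pixels.

    Zero-area (degenerate) boxes are permitted — detectors occasionally emit
    them and they must flow through the pipeline as non-candidates rather
    than crash it. Negative extents are rejected at construction.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min:
            raise ValueError(
                f"invalid box: x_max ({self.x_max}) < x_min ({self.x_min})"
            )
        if self.y_max < self.y_min:
            raise ValueError(
                f"invalid box: y_max ({self.y_max}) < y_min ({self.y_min})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def scale(self, s: float) -> "Box":
        """Uniformly scale about the image origin by ``s > 0``."""
        if s <= 0:
            raise ValueError(f"scale factor must be positive, got {s}")
        return Box(self.x_min * s, self.y_min * s, self.x_max * s, self.y_max * s)


def intersection_area(a: Box, b: Box) -> float:
    """Overlap area of two boxes in squared pixels; symmetric, ≥ 0."""
    dx = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    dy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if dx <= 0.0 or dy <= 0.0:
        return 0.0
    return dx * dy


def iou(a: Box, b: Box) -> float:
    """Intersection over union, in [0, 1].

    This is the proximity measure between a pig head and the feeder bin:
    heads whose IoU with a feeder exceeds the gate threshold are candidate
    feeding pigs. Two zero-area boxes have IoU 0 by convention (degenerate
    detections are non-candidates, not errors).
    """
    inter = intersection_area(a, b)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def coverage_ratio(head: Box, body: Box) -> float:
    """Head–body intersection area divided by head area, in [0, 1].

    Normalising by the head (not the union) makes the measure invariant to
    pig size: a fully visible head lying inside its body scores 1 regardless
    of how large the pig is. Not symmetric in its arguments.
    """
    if head.area <= 0.0:
        raise ValueError(
            "coverage_ratio: head box has zero area and cannot anchor a pig "
            f"(head={head})"
        )
    return intersection_area(head, body) / head.area


def center(b: Box) -> tuple[float, float]:
    """Box center ``((x_min+x_max)/2, (y_min+y_max)/2)``."""
    return ((b.x_min + b.x_max) / 2.0, (b.y_min + b.y_max) / 2.0)


def major_axis_endpoints(b: Box) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the segment through the center along the box's longer side.

    A pig body box is roughly 2:1, so its major axis approximates the spine;
    the head sits at one of its ends, which is what the farthest-center rule
    in head–body mapping exploits. On an exact tie (square box) the
    horizontal axis is returned — a fixed convention chosen for determinism.
    """
    cx, cy = center(b)
    if b.width >= b.height:
        return ((b.x_min, cy), (b.x_max, cy))
    return ((cx, b.y_min), (cx, b.y_max))
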