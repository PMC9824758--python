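"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from feedcount import Box, Detection, Scene


def raster_intersection_area(a: Box, b: Box) -> float:
    """Count unit grid cells covered by both boxes (integer coordinates).

    Independent rasterization oracle: a cell (i, j) is covered by a box when
    i ∈ [x_min, x_max) and j ∈ [y_min, y_max). For integer-corner boxes the
    covered-cell count equals the geometric intersection area exactly.
    """
    count = 0
    x_lo = int(min(a.x_min, b.x_min))
    x_hi = int(max(a.x_max, b.x_max))
    y_lo = int(min(a.y_min, b.y_min))
    y_hi = int(max(a.y_max, b.y_max))
    for i in range(x_lo, x_hi):
        for j in range(y_lo, y_hi):
            in_a = a.x_min <= i < a.x_max and a.y_min <= j < a.y_max
            in_b = b.x_min <= i < b.x_max and b.y_min <= j < b.y_max
            if in_a and in_b:
                count += 1
    return float(count)


def raster_iou(a: Box, b: Box) -> float:
    inter = raster_intersection_area(a, b)
    union = raster_intersection_area(a, a) + raster_intersection_area(b, b) - inter
    return inter / union if union > 0 else 0.0


def brute_force_head_body_mapping(
    heads: list[tuple[float, float]],
    bodies: list[tuple[float, float]],
    overlaps: set[tuple[int, int]],
    head_order: list[int],
) -> dict[int, int]:
    """Literal trace of the greedy farthest-center association.

    Works on pre-computed centers and an overlap relation, sharing no code
    with the implementation. Processes heads in the given order; for each,
    picks the not-yet-consumed overlapping body whose center is farthest
    (ties toward the lower body index) and consumes it.
    """
    consumed: set[int] = set()
    assignment: dict[int, int] = {}
    for i in head_order:
        best_j, best_d = -1, -1.0
        for j in range(len(bodies)):
            if j in consumed or (i, j) not in overlaps:
                continue
            d = math.dist(heads[i], bodies[j])
            if d > best_d:
                best_d, best_j = d, j
        if best_j >= 0:
            consumed.add(best_j)
            assignment[i] = best_j
    return assignment


def scale_scene(scene: Scene, s: float) -> Scene:
    """Uniformly scale every box (and the image frame) by ``s``."""
    return Scene(
        image_id=scene.image_id,
        width=scene.width * s,
        height=scene.height * s,
        timestamp=scene.timestamp,
        detections=[replace(d, box=d.box.scale(s)) for d in scene.detections],
    )


def random_int_box(rng: np.random.Generator, lo: int = 0, hi: int = 30) -> Box:
    x = sorted(rng.integers(lo, hi + 1, size=2).tolist())
    y = sorted(rng.integers(lo, hi + 1, size=2).tolist())
    return Box(float(x[0]), float(y[0]), float(x[1]), float(y[1]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220238)
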