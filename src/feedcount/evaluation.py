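"""Scoring predicted feeding counts against ground truth.

The metric is the sum of absolute difference ratio (SADR):

    SADR = Σ_i |G_i − P_i| / T

where G_i and P_i are the actual and predicted numbers of feeding pigs in
image i and T is the barn population. The sum runs over all scored images
and is normalised once by T — it is *not* averaged per image, so SADR grows
with the number of evaluated images for a fixed error rate. Lower is
better; 0 means every image was counted exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import CountRecord

__all__ = ["EvalResult", "sadr", "per_image_errors"]


@dataclass(frozen=True)
class EvalResult:
    """SADR and its ingredients for one batch of scored images."""

    sadr: float
    total_abs_error: int
    n_images: int
    barn_population: int

    @property
    def sadr_rounded(self) -> float:
        """SADR rounded to two decimals, the conventional reporting precision."""
        return round(self.sadr, 2)

    def summary(self) -> str:
        return (
            f"SADR {self.sadr_rounded} ({self.sadr:.6g} unrounded): "
            f"total |G−P| = {self.total_abs_error} over {self.n_images} images, "
            f"barn population T = {self.barn_population}"
        )

    def to_dict(self) -> dict:
        return {
            "sadr": self.sadr,
            "sadr_rounded": self.sadr_rounded,
            "total_abs_error": self.total_abs_error,
            "n_images": self.n_images,
            "barn_population": self.barn_population,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def per_image_errors(records: Sequence[CountRecord]) -> list[tuple[str, int]]:
    """Per-image absolute error |actual − predicted|, in input order."""
    errors = []
    for rec in records:
        if rec.actual is None:
            raise ValueError(
                f"record {rec.image_id!r} has no ground-truth count; "
                "evaluation needs 'actual' on every record"
            )
        errors.append((rec.image_id, abs(rec.actual - rec.predicted)))
    return errors


def sadr(records: Sequence[CountRecord], barn_population: int) -> EvalResult:
    """Compute SADR over a batch of records with ground truth.

    ``barn_population`` is the number of pigs housed in the barn — a
    husbandry fact supplied by the user, not something inferred from
    detections.
    """
    if barn_population <= 0:
        raise ValueError(f"barn_population must be > 0, got {barn_population}")
    errors = per_image_errors(records)
    total = sum(e for _, e in errors)
    return EvalResult(
        sadr=total / barn_population,
        total_abs_error=total,
        n_images=len(records),
        barn_population=barn_population,
    )
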