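"""Temporal aggregation of per-image feeding counts.

Barn cameras capture one frame per hour; over days those per-image counts
reveal the herd's feeding rhythm. Two summaries are produced: the diurnal
profile (mean count per hour of day — pigs show morning and afternoon
feeding peaks) and the daily series (total feeding events per calendar
day), a coarse welfare signal since sick animals feed less.

Timestamps are taken as local barn time; no timezone conversion is applied.
The diurnal profile averages (rather than sums) within each hour-of-day bin
so that unequal coverage across days does not bias the curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import CountRecord

__all__ = [
    "DiurnalProfile",
    "DailySeries",
    "diurnal_profile",
    "daily_series",
    "write_profile_csv",
    "write_series_csv",
    "plot_feeding_pattern",
]


def _require_timestamps(records: Sequence[CountRecord]) -> None:
    for rec in records:
        if rec.timestamp is None:
            raise ValueError(
                f"record {rec.image_id!r} has no timestamp; aggregation needs one "
                "on every record (supply a manifest)"
            )


@dataclass(frozen=True)
class DiurnalProfile:
    """Mean predicted count per hour of day; hours never observed are absent."""

    mean_count: dict[int, float]
    n_images: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        hours = sorted(self.mean_count)
        return pd.DataFrame(
            {
                "hour": hours,
                "mean_count": [self.mean_count[h] for h in hours],
                "n_images": [self.n_images[h] for h in hours],
            }
        )


@dataclass(frozen=True)
class DailySeries:
    """Total feeding events per calendar day, dates ascending.

    A day with zero activity is data, not absence: its date stays in the
    series with total 0.
    """

    totals: dict[date, int]

    def to_frame(self) -> pd.DataFrame:
        days = sorted(self.totals)
        return pd.DataFrame({"date": days, "total_count": [self.totals[d] for d in days]})


def diurnal_profile(records: Sequence[CountRecord]) -> DiurnalProfile:
    """Bucket records by hour of day and average the predicted counts."""
    _require_timestamps(records)
    if not records:
        return DiurnalProfile(mean_count={}, n_images={})
    df = pd.DataFrame(
        {
            "hour": [r.timestamp.hour for r in records],  # type: ignore[union-attr]
            "predicted": [r.predicted for r in records],
        }
    )
    grouped = df.groupby("hour")["predicted"]
    return DiurnalProfile(
        mean_count=grouped.mean().to_dict(),
        n_images=grouped.size().to_dict(),
    )


def daily_series(records: Sequence[CountRecord]) -> DailySeries:
    """Sum predicted counts per calendar date."""
    _require_timestamps(records)
    if not records:
        return DailySeries(totals={})
    df = pd.DataFrame(
        {
            "date": [r.timestamp.date() for r in records],  # type: ignore[union-attr]
            "predicted": [r.predicted for r in records],
        }
    )
    totals = df.groupby("date")["predicted"].sum().to_dict()
    return DailySeries(totals={d: int(v) for d, v in sorted(totals.items())})


def write_profile_csv(profile: DiurnalProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


def write_series_csv(series: DailySeries, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "total_count"])
        for d in sorted(series.totals):
            writer.writerow([d.isoformat(), series.totals[d]])


def plot_feeding_pattern(
    profile: DiurnalProfile, series: DailySeries, path: str | Path
) -> None:
    """Two-panel figure: diurnal profile (left) and daily series (right)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(11, 4))
    hours = sorted(profile.mean_count)
    ax0.bar(hours, [profile.mean_count[h] for h in hours], color="#4477aa")
    ax0.set_xlabel("hour of day")
    ax0.set_ylabel("mean feeding pigs per image")
    ax0.set_title("Diurnal feeding profile")
    ax0.set_xticks(range(0, 24, 3))

    days = sorted(series.totals)
    ax1.plot(days, [series.totals[d] for d in days], marker="o", color="#cc6677")
    ax1.set_xlabel("date")
    ax1.set_ylabel("feeding events per day")
    ax1.set_title("Daily feeding events")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
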