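"""Surveillance sampling design: per-area video schedules and count tables.

The measurement design intercepts a one-minute surveillance video every half
hour in each monitored area, extracts frames at 0.2 FPS (one image every 5 s,
capped at 10 images per video), and summarizes each half-hourly slot by the
mean head count over its frames.  Areas operating around the clock yield 48
videos per day; areas open 8:00-18:00 yield 21 (the half-hour grid includes
both endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OperatingHours",
    "SamplingPlan",
    "CountTable",
    "videos_per_day",
    "weekly_video_count",
    "frame_times",
    "aggregate_slot",
    "build_count_table",
]

_MIN_PER_DAY = 24 * 60


@dataclass(frozen=True)
class OperatingHours:
    """Daily operating window in minutes since midnight.

    ``all_day`` areas are sampled on the full 48-point half-hour grid
    (00:00 .. 23:30).  Bounded windows are sampled inclusively at both the
    opening and closing half-hours, so 8:00-18:00 gives 21 grid points.
    """

    open_minute: int = 0
    close_minute: int = _MIN_PER_DAY
    all_day: bool = False

    def __post_init__(self) -> None:
        if self.all_day:
            return
        if not (0 <= self.open_minute <= self.close_minute <= _MIN_PER_DAY):
            raise ValueError(
                f"malformed operating hours: open={self.open_minute} "
                f"close={self.close_minute}"
            )
        if self.open_minute % 30 or self.close_minute % 30:
            raise ValueError("operating hours must align to the half-hour grid")

    @classmethod
    def parse(cls, text: str) -> "OperatingHours":
        """Parse ``"24h"`` or ``"8:00-18:00"`` style specifications."""
        text = text.strip().lower()
        if text in {"24h", "24", "all", "all_day"}:
            return cls(all_day=True)
        try:
            lo, hi = text.split("-")
            return cls(open_minute=_parse_clock(lo), close_minute=_parse_clock(hi))
        except ValueError as exc:
            raise ValueError(f"malformed operating-hours spec {text!r}") from exc

    def slot_minutes(self) -> list[int]:
        """Half-hourly sampling instants (minutes since midnight)."""
        if self.all_day:
            return list(range(0, _MIN_PER_DAY, 30))
        return list(range(self.open_minute, self.close_minute + 1, 30))


def _parse_clock(text: str) -> int:
    h, m = text.strip().split(":")
    return int(h) * 60 + int(m)


HOURS_24H = OperatingHours(all_day=True)
HOURS_DAY_SHIFT = OperatingHours(open_minute=8 * 60, close_minute=18 * 60)


@dataclass(frozen=True)
class SamplingPlan:
    """One half-hourly one-minute video per slot, frames extracted at 0.2 FPS.

    ``frames_per_video`` caps extraction: 60 s at 0.2 FPS admits 12 grid
    points, of which the first 10 (offsets 0-45 s) are kept.
    """

    interval_min: float = 30.0
    video_length_s: float = 60.0
    fps: float = 0.2
    frames_per_video: int = 10

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.video_length_s <= 0 or self.frames_per_video < 1:
            raise ValueError("sampling plan parameters must be positive")
        if self.interval_min * 60 <= self.video_length_s:
            raise ValueError("sampling interval must exceed the video length")
        # schedule feasibility: the capped frame grid must fit in one video
        if self.frames_per_video * (1.0 / self.fps) > self.video_length_s + 1.0 / self.fps:
            raise ValueError(
                f"{self.frames_per_video} frames at {self.fps} FPS do not fit "
                f"in a {self.video_length_s}-second video"
            )


DEFAULT_PLAN = SamplingPlan()


def videos_per_day(hours: OperatingHours, plan: SamplingPlan = DEFAULT_PLAN) -> int:
    """Number of half-hourly videos one area contributes per day."""
    return len(hours.slot_minutes())


def weekly_video_count(
    areas: list[OperatingHours], days: int, plan: SamplingPlan = DEFAULT_PLAN
) -> int:
    """Total videos over ``days`` days across all areas."""
    if days < 1:
        raise ValueError("days must be >= 1")
    return sum(videos_per_day(h, plan) * days for h in areas)


def frame_times(plan: SamplingPlan = DEFAULT_PLAN) -> list[float]:
    """Within-video frame offsets in seconds (0, 5, ..., 45 on the default plan)."""
    step = 1.0 / plan.fps
    offsets = [i * step for i in range(plan.frames_per_video)]
    if offsets[-1] > plan.video_length_s:
        raise ValueError("frame grid exceeds video length")
    return offsets


def aggregate_slot(counts) -> float:
    """Mean people count over one slot's extracted frames."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty slot")
    return float(arr.mean())


@dataclass
class CountTable:
    """Areas x (day, slot) grid of per-slot mean people counts.

    ``cells`` is indexed by area name with a (day, slot-minute) column
    MultiIndex.  Margins are always recomputed from the cells, never trusted
    from input.
    """

    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.cells.values < 0).any():
            raise ValueError("count table cells must be non-negative")

    @property
    def areas(self) -> list[str]:
        return list(self.cells.index)

    def daily_totals(self) -> pd.DataFrame:
        """Per-area, per-day sums of slot means (person-time per day)."""
        return self.cells.T.groupby(level="day", sort=False).sum().T

    def weekly_totals(self) -> pd.Series:
        """Per-area sums over the whole table."""
        return self.cells.sum(axis=1)

    def day_margins(self) -> pd.Series:
        """Per-day sums over all areas."""
        return self.daily_totals().sum(axis=0)

    def grand_total(self) -> float:
        return float(self.cells.values.sum())

    def slot_series(self, area: str, day: str) -> pd.Series:
        return self.cells.loc[area, day]

    def to_weekly_report(self, decimals: int | None = None) -> pd.DataFrame:
        """Days x areas report with Sum row and column, mirroring a weekly census."""
        daily = self.daily_totals().T  # days x areas
        if decimals is not None:
            daily = daily.round(decimals)
        report = daily.copy()
        report["Sum"] = report.sum(axis=1)
        report.loc["Sum"] = report.sum(axis=0)
        return report

    @classmethod
    def from_slot_means(
        cls, entries: list[tuple[str, str, int, float]]
    ) -> "CountTable":
        """Build from (area, day, slot_minute, mean_count) tuples."""
        seen: set[tuple[str, str, int]] = set()
        for area, day, slot, _ in entries:
            key = (area, day, slot)
            if key in seen:
                raise ValueError(f"duplicate (area, day, slot) entry: {key}")
            seen.add(key)
        df = pd.DataFrame(entries, columns=["area", "day", "slot", "count"])
        wide = df.pivot(index="area", columns=["day", "slot"], values="count")
        wide = wide.fillna(0.0)
        wide.columns = wide.columns.set_names(["day", "slot"])
        return cls(wide)

    @classmethod
    def from_daily_totals(cls, daily: pd.DataFrame) -> "CountTable":
        """Build from an areas x days table of daily totals.

        Each daily total is stored as a single one-slot cell, so slot-level
        structure is absent but all margins are exact.
        """
        cols = pd.MultiIndex.from_arrays(
            [list(daily.columns), [0] * daily.shape[1]], names=["day", "slot"]
        )
        wide = pd.DataFrame(daily.values.astype(float), index=daily.index, columns=cols)
        return cls(wide)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [(day, int(slot)) for day, slot in df.columns], names=["day", "slot"]
        )
        return cls(df)


def build_count_table(entries: list[tuple[str, str, int, float]]) -> CountTable:
    """Assemble per-slot mean counts into a :class:`CountTable` with margins."""
    return CountTable.from_slot_means(entries)
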