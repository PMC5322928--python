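"""Ground-truth series and detection-vs-truth metrics.

Two kinds of field data anchor the social-media signal.  For the moth,
repeated transect surveys measure the volume of aestivating clusters
(width x height x depth per patch, summed per survey); the series is
expressed as percent of the season's total volume.  For the bird,
long-running monthly garden counts are summed across years into a
12-month percentage profile of the migration season.

Detection is judged seasonally: the species arrives in the Southern
Hemisphere Spring, so an upper CUSUM violation during September-November
counts as detecting that season's arrival, and upper violations outside
every Spring window are out-of-season alarms.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tweetstore import CoveragePeriod

__all__ = [
    "SurveyRecord",
    "GroundTruthSeries",
    "MonthlyProfile",
    "SeasonWindow",
    "SeasonResult",
    "DetectionMetrics",
    "percent_volume",
    "monthly_profile",
    "spring_windows",
    "evaluate",
]


@dataclass(frozen=True)
class SurveyRecord:
    """One site visit: every moth patch measured as (width, height, depth) cm."""

    survey_date: date
    site_id: str
    patches: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for dims in self.patches:
            if len(dims) != 3 or any(d <= 0 for d in dims):
                raise ValueError("patch dimensions must be three positive numbers")

    @property
    def volume(self) -> float:
        return sum(w * h * d for w, h, d in self.patches)


@dataclass(frozen=True)
class GroundTruthSeries:
    survey_dates: tuple[date, ...]
    percent_of_total_volume: np.ndarray
    true_arrival_date: date | None = None

    def __post_init__(self) -> None:
        pct = np.asarray(self.percent_of_total_volume, float)
        if (pct < 0).any():
            raise ValueError("percentages must be non-negative")
        if abs(pct.sum() - 100.0) > 1e-6:
            raise ValueError("percentages must sum to 100")
        object.__setattr__(self, "percent_of_total_volume", pct)


@dataclass(frozen=True)
class MonthlyProfile:
    """Percent of total sightings per calendar month (12 entries, sum 100)."""

    percent_by_month: np.ndarray

    def __post_init__(self) -> None:
        pct = np.asarray(self.percent_by_month, float)
        if pct.shape != (12,):
            raise ValueError("profile needs exactly 12 monthly entries")
        if (pct < 0).any():
            raise ValueError("percentages must be non-negative")
        if abs(pct.sum() - 100.0) > 1e-6:
            raise ValueError("percentages must sum to 100")
        object.__setattr__(self, "percent_by_month", pct)

    def __getitem__(self, month: int) -> float:
        if not 1 <= month <= 12:
            raise IndexError("month must be 1..12")
        return float(self.percent_by_month[month - 1])


@dataclass(frozen=True)
class SeasonWindow:
    """Southern-Hemisphere Spring of one year: 1 Sep - 30 Nov, inclusive."""

    year: int

    @property
    def start(self) -> date:
        return date(self.year, 9, 1)

    @property
    def end(self) -> date:
        return date(self.year, 11, 30)

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end

    def overlaps_week(self, week_start: date) -> bool:
        return week_start <= self.end and week_start + timedelta(days=6) >= self.start


@dataclass(frozen=True)
class SeasonResult:
    year: int
    detected: bool
    delay_days: int | None  # from true arrival to first in-window upper week


@dataclass(frozen=True)
class DetectionMetrics:
    seasons: tuple[SeasonResult, ...]
    out_of_season_upper: int

    @property
    def n_detected(self) -> int:
        return sum(s.detected for s in self.seasons)


def percent_volume(
    surveys: Sequence[SurveyRecord], true_arrival_date: date | None = None
) -> GroundTruthSeries:
    """Total patch volume per survey date, as percent of the season total.

    Sites surveyed on the same date pool into one survey; normalization is
    over all surveys of the season so the series sums to 100.
    """
    if not surveys:
        raise ValueError("need at least one survey")
    totals: dict[date, float] = {}
    for rec in surveys:
        totals[rec.survey_date] = totals.get(rec.survey_date, 0.0) + rec.volume
    dates = tuple(sorted(totals))
    volumes = np.array([totals[d] for d in dates])
    grand = volumes.sum()
    if grand == 0.0:
        raise ValueError("all survey volumes are zero: no season signal")
    return GroundTruthSeries(dates, 100.0 * volumes / grand, true_arrival_date)


def monthly_profile(records: Iterable[tuple[int, float]]) -> MonthlyProfile:
    """Sum (month, count) pairs across years and normalize to percent."""
    sums = np.zeros(12)
    for month, count in records:
        if not 1 <= month <= 12:
            raise ValueError(f"month {month} out of range")
        if count < 0:
            raise ValueError("counts must be non-negative")
        sums[month - 1] += count
    total = sums.sum()
    if total == 0.0:
        raise ValueError("all counts are zero")
    return MonthlyProfile(100.0 * sums / total)


def spring_windows(period: CoveragePeriod) -> list[SeasonWindow]:
    """One window per 1 Sep - 30 Nov interval intersecting the period."""
    windows = []
    for year in range(period.start.year - 1, period.end.year + 1):
        w = SeasonWindow(year)
        if w.start < period.end and w.end >= period.start:
            windows.append(w)
    return windows


def _arrival_for(
    year: int,
    truth: GroundTruthSeries | Mapping[int, date] | Sequence[date] | date | None,
) -> date | None:
    if truth is None:
        return None
    if isinstance(truth, GroundTruthSeries):
        arr = truth.true_arrival_date
        return arr if arr is not None and arr.year == year else None
    if isinstance(truth, date):
        return truth if truth.year == year else None
    if isinstance(truth, Mapping):
        return truth.get(year)
    for d in truth:
        if d.year == year:
            return d
    return None


def evaluate(
    events: Sequence[tuple[date, str]],
    windows: Sequence[SeasonWindow],
    truth: GroundTruthSeries | Mapping[int, date] | Sequence[date] | date | None = None,
) -> DetectionMetrics:
    """Score detected events against the seasonal windows and true arrivals.

    A season is detected iff at least one *upper* violation falls in a week
    overlapping its window; the delay is counted in days from the true
    arrival (when known) to the start of the first such week.  Upper
    violations overlapping no window are out-of-season alarms.  The result
    is invariant to the ordering of the event list.
    """
    upper_weeks = sorted(ws for ws, direction in events if direction == "upper")
    seasons = []
    for window in windows:
        in_window = [ws for ws in upper_weeks if window.overlaps_week(ws)]
        detected = bool(in_window)
        delay = None
        arrival = _arrival_for(window.year, truth)
        if detected and arrival is not None:
            delay = (in_window[0] - arrival).days
        seasons.append(SeasonResult(window.year, detected, delay))
    out_of_season = sum(
        not any(w.overlaps_week(ws) for w in windows) for ws in upper_weeks
    )
    return DetectionMetrics(tuple(seasons), out_of_season)
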