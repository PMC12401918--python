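"""Daily activity time budgets and the reference routine.

Labeled intervals are summed into per-day activity durations, normalized to
proportions A_i (fraction of that day's total labeled time), and averaged
across a baseline window into a reference routine with proportions R_i.
Both A and R are probability vectors over the activity set, which is what a
weighted absolute-deviation comparison between a day and the routine
requires.

Unlabeled time (no activity annotation) is excluded from the denominator:
A_i is the share of *labeled* time, not of the 24-hour day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Literal, Sequence

import pandas as pd

from .event_io import ActivityInterval

__all__ = [
    "DailyActivityProfile",
    "ReferenceRoutine",
    "EmptyDayError",
    "aggregate_daily_durations",
    "normalize_proportions",
    "build_reference_routine",
    "profiles_to_frame",
]

_SUM_TOL = 1e-9


class EmptyDayError(ValueError):
    """A day with zero total labeled time cannot be normalized or scored."""


@dataclass
class DailyActivityProfile:
    """Per-day activity durations (seconds) and normalized proportions A_i."""

    day: date
    durations: dict[str, float]
    proportions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for activity, seconds in self.durations.items():
            if seconds < 0:
                raise ValueError(f"negative duration for {activity!r}: {seconds}")
        if self.proportions is not None and self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"proportions sum to {total}, expected 1")

    @property
    def total_seconds(self) -> float:
        return sum(self.durations.values())


@dataclass
class ReferenceRoutine:
    """Reference proportions R_i over a baseline window of ``n_days`` days."""

    proportions: dict[str, float]
    n_days: int

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("reference routine needs at least one day")
        for activity, p in self.proportions.items():
            if p < 0:
                raise ValueError(f"negative reference proportion for {activity!r}")
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"reference proportions sum to {total}, expected 1")


def aggregate_daily_durations(
    intervals: Iterable[ActivityInterval],
) -> list[DailyActivityProfile]:
    """Sum interval durations into one duration map per source day.

    Days with no intervals are simply absent from the output; an empty input
    yields an empty list.
    """
    per_day: dict[date, dict[str, float]] = {}
    for iv in intervals:
        day_map = per_day.setdefault(iv.source_day, {})
        day_map[iv.activity] = day_map.get(iv.activity, 0.0) + iv.duration_s
    return [
        DailyActivityProfile(day=d, durations=per_day[d]) for d in sorted(per_day)
    ]


def normalize_proportions(profile: DailyActivityProfile) -> DailyActivityProfile:
    """Fill in A_i = duration_i / total labeled seconds for the day.

    Raises :class:`EmptyDayError` when the day has zero labeled time; such
    days are excluded from scoring by the callers and reported.
    """
    total = profile.total_seconds
    if total <= 0:
        raise EmptyDayError(f"day {profile.day} has no labeled activity time")
    proportions = {a: s / total for a, s in profile.durations.items()}
    return DailyActivityProfile(
        day=profile.day, durations=dict(profile.durations), proportions=proportions
    )


def build_reference_routine(
    profiles: Sequence[DailyActivityProfile],
    method: Literal["pooled_mean", "mean_of_proportions"] = "pooled_mean",
) -> ReferenceRoutine:
    """Average daily profiles into reference proportions R_i.

    ``pooled_mean`` (default): R_i is the mean daily duration of activity i
    divided by the sum of those mean durations, so that sum(R) == 1 exactly
    and R is comparable to any day's A as a distribution.  An activity absent
    on some day contributes zero seconds to that day's term of the mean.

    ``mean_of_proportions``: R_i is the across-day average of each day's own
    A_i.  The two coincide when every day has the same total labeled time and
    differ otherwise; the pooled form weights longer days more.
    """
    if not profiles:
        raise ValueError("cannot build a reference routine from zero days")
    n_days = len(profiles)
    activities = sorted({a for p in profiles for a in p.durations})
    if not activities:
        raise ValueError("profiles contain no activities")

    if method == "pooled_mean":
        mean_durations = {
            a: sum(p.durations.get(a, 0.0) for p in profiles) / n_days
            for a in activities
        }
        total = sum(mean_durations.values())
        if total <= 0:
            raise EmptyDayError("baseline days have no labeled activity time")
        proportions = {a: m / total for a, m in mean_durations.items()}
    elif method == "mean_of_proportions":
        normalized = [
            p if p.proportions is not None else normalize_proportions(p)
            for p in profiles
        ]
        proportions = {
            a: sum(p.proportions.get(a, 0.0) for p in normalized) / n_days  # type: ignore[union-attr]
            for a in activities
        }
    else:
        raise ValueError(f"unknown reference method {method!r}")
    return ReferenceRoutine(proportions=proportions, n_days=n_days)


def profiles_to_frame(
    profiles: Sequence[DailyActivityProfile], *, values: Literal["durations", "proportions"] = "durations"
) -> pd.DataFrame:
    """Tabulate profiles as one row per day, one column per activity."""
    rows = {}
    for p in profiles:
        if values == "durations":
            rows[p.day] = p.durations
        else:
            if p.proportions is None:
                p = normalize_proportions(p)
            rows[p.day] = p.proportions
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    frame.index.name = "day"
    return frame
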