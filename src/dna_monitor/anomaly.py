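"""Cross-score analyses: flag overlap, night-time counts, long appliance use.

Three descriptive views complement the per-day WADI and per-night SDP flags:

- the overlap of the two flagged day sets (days anomalous in both activity
  budget and sleep carry more signal than either alone);
- per-night counts of selected events inside a night window, e.g. bathroom
  motion firings between 22:00 and 06:00 (excessive night bathroom visits
  can indicate urinary infections or dehydration);
- nights on which a target activity (typically stove use) accumulates more
  than a duration threshold inside the night window, paired with that
  night's sleep duration (prolonged night-time cooking on short-sleep nights
  suggests night wandering).

"Night" defaults to the half-open window [22:00, 06:00) and every night
quantity is attributed to the noon-anchored date on which the night began.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .event_io import ActivityInterval, EventStream, SensorEvent, assign_day, NOON_ANCHOR
from .sleep import SleepSession
from .wadi import DeviationRecord

__all__ = [
    "OverlapReport",
    "NightEpisode",
    "DEFAULT_NIGHT_WINDOW",
    "overlap_days",
    "night_activity_count",
    "long_duration_episodes",
    "sleep_usage_table",
]

DEFAULT_NIGHT_WINDOW: tuple[time, time] = (time(22, 0), time(6, 0))


@dataclass
class OverlapReport:
    """Flagged-day sets of two scores and their intersection."""

    wadi_flagged: set[date]
    sdp_flagged: set[date]
    overlap: set[date]
    flag_fractions: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class NightEpisode:
    """Total in-window seconds of one activity on one night."""

    night: date
    label: str
    total_seconds: float
    event_count: int
    flagged: bool = False


def overlap_days(
    wadi_records: Sequence[DeviationRecord],
    sdp_records: Sequence[DeviationRecord],
) -> OverlapReport:
    """Intersect the flagged day sets of the two scores.

    The flag fraction of each score is computed over that score's own
    covered days, so the two series may span different date ranges.
    """
    wadi_flagged = {r.day for r in wadi_records if r.flagged}
    sdp_flagged = {r.day for r in sdp_records if r.flagged}
    fractions = {
        "wadi": len(wadi_flagged) / len(wadi_records) if wadi_records else 0.0,
        "sdp": len(sdp_flagged) / len(sdp_records) if sdp_records else 0.0,
    }
    return OverlapReport(
        wadi_flagged=wadi_flagged,
        sdp_flagged=sdp_flagged,
        overlap=wadi_flagged & sdp_flagged,
        flag_fractions=fractions,
    )


def _in_window(clock: time, window: tuple[time, time]) -> bool:
    start, end = window
    if start == end:
        raise ValueError("degenerate night window (start == end)")
    if start < end:
        return start <= clock < end
    return clock >= start or clock < end  # wraps midnight


def night_activity_count(
    stream: EventStream | Iterable[SensorEvent],
    targets: set[str],
    window: tuple[time, time] = DEFAULT_NIGHT_WINDOW,
) -> pd.Series:
    """Per-night count of target events starting inside the night window.

    An event matches when its sensor id or its activity label is in
    ``targets``.  The window is half-open and may wrap midnight; each match
    is attributed to the noon-anchored night.  Nights in the stream's
    covered range with no matching event are reported as 0.
    """
    start, end = window
    if start == end:
        raise ValueError("degenerate night window (start == end)")
    events = stream.events if isinstance(stream, EventStream) else list(stream)
    counts: dict[date, int] = {}
    observed: set[date] = set()
    for event in events:
        night = assign_day(event.timestamp, NOON_ANCHOR)
        observed.add(night)
        if event.sensor_id in targets or (event.activity_label in targets):
            if _in_window(event.timestamp.time(), window):
                counts[night] = counts.get(night, 0) + 1
    if not observed:
        return pd.Series(dtype=int, name="count")
    d0, d1 = min(observed), max(observed)
    nights = [d0 + timedelta(days=k) for k in range((d1 - d0).days + 1)]
    return pd.Series(
        [counts.get(n, 0) for n in nights], index=pd.Index(nights, name="night"),
        name="count",
    )


def _night_window_bounds(night: date, window: tuple[time, time]) -> tuple[datetime, datetime]:
    """Absolute instants of a clock window on a given noon-anchored night.

    Clock times at or after noon fall on the night's own date, earlier ones
    on the following morning; an end not after the start rolls to the next
    day (the wrap-around case).
    """
    start, end = window
    w0 = datetime.combine(night if start >= NOON_ANCHOR else night + timedelta(days=1), start)
    w1 = datetime.combine(night if end >= NOON_ANCHOR else night + timedelta(days=1), end)
    if w1 <= w0:
        w1 += timedelta(days=1)
    return w0, w1


def long_duration_episodes(
    intervals: Sequence[ActivityInterval],
    activity: str,
    window: tuple[time, time] = DEFAULT_NIGHT_WINDOW,
    min_seconds: float = 1000.0,
) -> list[NightEpisode]:
    """Total in-window seconds of ``activity`` per night; flag long totals.

    Interval time is clipped to the night window before summing, so an
    episode straddling the window boundary contributes only its in-window
    part.  A night is flagged when its total strictly exceeds
    ``min_seconds``.  Only nights with positive in-window time are emitted.
    """
    if min_seconds <= 0:
        raise ValueError("min_seconds must be positive")
    if window[0] == window[1]:
        raise ValueError("degenerate night window (start == end)")
    per_night: dict[date, tuple[float, int]] = {}
    for iv in intervals:
        if iv.activity != activity:
            continue
        # an interval can touch the window of its own night or a neighbor's
        for night in {
            assign_day(iv.start, NOON_ANCHOR) + timedelta(days=k) for k in (-1, 0, 1)
        }:
            w0, w1 = _night_window_bounds(night, window)
            lo, hi = max(iv.start, w0), min(iv.end, w1)
            if hi > lo:
                total, count = per_night.get(night, (0.0, 0))
                per_night[night] = (total + (hi - lo).total_seconds(), count + 1)
    return [
        NightEpisode(
            night=n,
            label=activity,
            total_seconds=total,
            event_count=count,
            flagged=total > min_seconds,
        )
        for n, (total, count) in sorted(per_night.items())
    ]


def sleep_usage_table(
    episodes: Sequence[NightEpisode],
    sessions: Sequence[SleepSession],
) -> pd.DataFrame:
    """Pair nightly appliance-use totals with sleep duration, per night.

    Returns a night-indexed table with columns ``usage_seconds`` and
    ``sleep_hours`` (NaN when that night has no sleep session) and, as a
    purely descriptive statistic, the Spearman rank correlation between the
    two columns in ``frame.attrs['spearman_rho']`` (NaN with < 3 complete
    nights).  No causal claim is implied.
    """
    sleep_by_night = {s.night: s.duration_s / 3600.0 for s in sessions}
    rows = {
        e.night: {
            "usage_seconds": e.total_seconds,
            "sleep_hours": sleep_by_night.get(e.night, float("nan")),
            "flagged": e.flagged,
        }
        for e in episodes
    }
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "night"
    complete = frame.dropna()
    if len(complete) >= 3:
        rho = stats.spearmanr(complete["usage_seconds"], complete["sleep_hours"]).statistic
    else:
        rho = float("nan")
    frame.attrs["spearman_rho"] = float(rho)
    return frame
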