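"""Nightly sleep sessions and the Sleep Deviation Patterns (SDP) score.

A night's sleep is summarized by three observables extracted from the labeled
event log: onset clock time O (hours on the 24 h circle), total sleep
duration D (seconds of Sleep-labeled time), and interruption count I
(Bed_Toilet_Transition occurrences within the sleep span).  Against a
personal reference (R_O, R_D, sigma_O, sigma_D) four metrics are derived:

- SOD, sleep onset deviation: circular distance between O and R_O in hours,
  ``min(|O - R_O|, 24 - |O - R_O|)``, in [0, 12].
- SDD, sleep duration deviation: ``|D - R_D| / 3600`` hours.
- SII, sleep interruption index: interruptions per hour of sleep, ``I / D_h``.
- SCI, sleep consistency index: ``max(0, 1 - sigma_O/24 - sigma_D/R_D)``,
  1 for a perfectly regular sleeper, clamped at 0.

These aggregate into the nightly score
``SDP = w1*SOD + w2*SDD + w3*SII + w4*(1 - SCI)``; lower is better.  The
components carry heterogeneous units (hours, per-hour, unitless) and are
summed as such by construction, so the weights double as unit conversions;
the defaults weight the four terms equally.

Onset statistics are circular: the mean and spread of onsets near midnight
must not be computed on raw clock hours (the naive mean of 23:30 and 00:30
is 12:00; the circular mean is 00:00).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_io import ActivityInterval, EventStream, NOON_ANCHOR, assign_day
from .wadi import DeviationRecord, ThresholdConfig, flag_days

__all__ = [
    "SleepSession",
    "SleepReference",
    "SleepMetrics",
    "SdpWeights",
    "extract_sleep_sessions",
    "build_sleep_reference",
    "compute_sod",
    "compute_sdd",
    "compute_sii",
    "compute_sci",
    "compute_sdp",
    "score_sleep_sessions",
    "flag_sleep_days",
]

SLEEP_LABEL = "Sleep"
INTERRUPTION_LABEL = "Bed_Toilet_Transition"

#: Fixed SDP threshold separating stable sleepers (scores below ~0.2) from
#: disrupted ones (scores above ~0.4).
DEFAULT_SDP_THRESHOLD = 0.4


@dataclass(frozen=True)
class SleepSession:
    """One night: onset O (clock hours), duration D (s), interruptions I."""

    night: date
    onset_hours: float
    duration_s: float
    interruptions: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_hours < 24.0:
            raise ValueError(f"onset must lie in [0, 24), got {self.onset_hours}")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        if self.interruptions < 0:
            raise ValueError("interruption count must be >= 0")


@dataclass(frozen=True)
class SleepReference:
    """Personal sleep baseline: mean onset/duration and their spreads."""

    onset_hours: float  # R_O
    duration_s: float  # R_D
    onset_sd_hours: float  # sigma_O, circular
    duration_sd_s: float  # sigma_D, population

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_hours < 24.0:
            raise ValueError("reference onset must lie in [0, 24)")
        if self.duration_s <= 0:
            raise ValueError("reference duration must be positive")
        if not 0.0 <= self.onset_sd_hours <= 12.0:
            raise ValueError("onset sd must lie in [0, 12]")
        if self.duration_sd_s < 0:
            raise ValueError("duration sd must be >= 0")


@dataclass(frozen=True)
class SleepMetrics:
    """Derived nightly metrics and their weighted aggregate."""

    sod: float
    sdd: float
    sii: float
    sci: float
    sdp: float


@dataclass(frozen=True)
class SdpWeights:
    """Weights of the four SDP components (all >= 0, default equal)."""

    w1: float = 0.25  # SOD
    w2: float = 0.25  # SDD
    w3: float = 0.25  # SII
    w4: float = 0.25  # 1 - SCI

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.w1 + self.w2 + self.w3 + self.w4


def _clock_hours(ts: datetime) -> float:
    return ts.hour + ts.minute / 60 + (ts.second + ts.microsecond / 1e6) / 3600


def extract_sleep_sessions(
    intervals: Sequence[ActivityInterval],
    stream: EventStream | None = None,
    *,
    sleep_label: str = SLEEP_LABEL,
    interruption_label: str = INTERRUPTION_LABEL,
    interruption_mode: Literal["label", "gap"] = "label",
    gap_max_s: float = 7200.0,
    anchor: time = NOON_ANCHOR,
    missing_nights: list[date] | None = None,
) -> list[SleepSession]:
    """Group Sleep-labeled intervals into noon-anchored nightly sessions.

    Per night: O is the clock time of the first Sleep interval's start, D the
    total Sleep-labeled seconds, and I either the number of
    ``interruption_label`` intervals starting within the span from first
    Sleep start to last Sleep end (``label`` mode, default) or the number of
    positive gaps of at most ``gap_max_s`` seconds between consecutive Sleep
    intervals (``gap`` mode; longer gaps count as separate settlings of the
    same night, not interruptions).

    Nights within the observed range that have no Sleep interval produce no
    session; pass ``missing_nights`` to collect them.
    """
    nights: dict[date, list[ActivityInterval]] = {}
    interrupters: dict[date, list[ActivityInterval]] = {}
    for iv in intervals:
        night = assign_day(iv.start, anchor)
        if iv.activity == sleep_label:
            nights.setdefault(night, []).append(iv)
        elif iv.activity == interruption_label:
            interrupters.setdefault(night, []).append(iv)

    sessions: list[SleepSession] = []
    for night in sorted(nights):
        spans = sorted(nights[night], key=lambda iv: iv.start)
        first_start = spans[0].start
        last_end = max(iv.end for iv in spans)
        duration = sum(iv.duration_s for iv in spans)
        if interruption_mode == "label":
            count = sum(
                1
                for iv in interrupters.get(night, [])
                if first_start <= iv.start <= last_end
            )
        elif interruption_mode == "gap":
            count = 0
            for prev, nxt in zip(spans, spans[1:]):
                gap = (nxt.start - prev.end).total_seconds()
                if 0 < gap <= gap_max_s:
                    count += 1
        else:
            raise ValueError(f"unknown interruption mode {interruption_mode!r}")
        sessions.append(
            SleepSession(
                night=night,
                onset_hours=_clock_hours(first_start),
                duration_s=duration,
                interruptions=count,
            )
        )

    if missing_nights is not None:
        observed_days = {assign_day(iv.start, anchor) for iv in intervals}
        if stream is not None and len(stream):
            observed_days |= {assign_day(e.timestamp, anchor) for e in stream}
        if observed_days:
            d0, d1 = min(observed_days), max(observed_days)
            span = [d0 + timedelta(days=k) for k in range((d1 - d0).days + 1)]
            missing_nights.extend(d for d in span if d not in nights)
    return sessions


def build_sleep_reference(sessions: Sequence[SleepSession]) -> SleepReference:
    """Circular mean/sd of onsets and mean/population-sd of durations.

    With a single session the spreads are 0.  The circular onset sd is
    clamped to 12 h (half the period): beyond that, onset carries no
    structure and SCI bottoms out anyway.
    """
    if not sessions:
        raise ValueError("cannot build a sleep reference from zero sessions")
    onsets = np.array([s.onset_hours for s in sessions], dtype=float)
    durations = np.array([s.duration_s for s in sessions], dtype=float)
    r_o = float(stats.circmean(onsets, high=24.0, low=0.0)) % 24.0
    sigma_o = float(stats.circstd(onsets, high=24.0, low=0.0))
    return SleepReference(
        onset_hours=r_o,
        duration_s=float(durations.mean()),
        onset_sd_hours=min(sigma_o, 12.0),
        duration_sd_s=float(durations.std(ddof=0)),
    )


def compute_sod(onset_hours: float, reference_onset_hours: float) -> float:
    """Circular distance between onsets on the 24 h clock, in [0, 12] hours."""
    for value in (onset_hours, reference_onset_hours):
        if not 0.0 <= value < 24.0:
            raise ValueError(f"onset must lie in [0, 24), got {value}")
    diff = abs(onset_hours - reference_onset_hours)
    return min(diff, 24.0 - diff)


def compute_sdd(duration_s: float, reference_duration_s: float) -> float:
    """Absolute duration deviation in hours: |D - R_D| / 3600."""
    if duration_s <= 0 or reference_duration_s <= 0:
        raise ValueError("durations must be positive")
    return abs(duration_s - reference_duration_s) / 3600.0


def compute_sii(interruptions: int, duration_hours: float) -> float:
    """Interruptions per hour of sleep: I / D_h."""
    if interruptions < 0:
        raise ValueError("interruption count must be >= 0")
    if duration_hours <= 0:
        raise ValueError(
            "sleep duration is zero; SII is undefined for this night "
            "(exclude and report it)"
        )
    return interruptions / duration_hours


def compute_sci(
    onset_sd_hours: float, duration_sd: float, reference_duration: float
) -> float:
    """max(0, 1 - sigma_O/24 - sigma_D/R_D); sigma_D and R_D in like units."""
    if onset_sd_hours < 0 or duration_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if reference_duration <= 0:
        raise ValueError("reference duration must be positive")
    return max(0.0, 1.0 - onset_sd_hours / 24.0 - duration_sd / reference_duration)


def compute_sdp(
    sod: float, sdd: float, sii: float, sci: float, weights: SdpWeights = SdpWeights()
) -> float:
    """Weighted aggregate w1*SOD + w2*SDD + w3*SII + w4*(1 - SCI)."""
    return (
        weights.w1 * sod + weights.w2 * sdd + weights.w3 * sii + weights.w4 * (1.0 - sci)
    )


def score_sleep_sessions(
    sessions: Sequence[SleepSession],
    reference: SleepReference | None = None,
    weights: SdpWeights = SdpWeights(),
) -> pd.DataFrame:
    """Per-night table of observables, the four metrics and the SDP score.

    When no reference is given it is built from the sessions themselves
    (the "own-baseline" configuration).  SCI depends only on the reference
    spreads, so it is constant across nights for a fixed reference.
    """
    if not sessions:
        raise ValueError("no sleep sessions to score")
    if reference is None:
        reference = build_sleep_reference(sessions)
    sci = compute_sci(reference.onset_sd_hours, reference.duration_sd_s, reference.duration_s)
    rows = []
    for s in sorted(sessions, key=lambda s: s.night):
        sod = compute_sod(s.onset_hours, reference.onset_hours)
        sdd = compute_sdd(s.duration_s, reference.duration_s)
        sii = compute_sii(s.interruptions, s.duration_s / 3600.0)
        rows.append(
            {
                "night": s.night,
                "onset_hours": s.onset_hours,
                "duration_s": s.duration_s,
                "interruptions": s.interruptions,
                "sod": sod,
                "sdd": sdd,
                "sii": sii,
                "sci": sci,
                "sdp": compute_sdp(sod, sdd, sii, sci, weights),
            }
        )
    return pd.DataFrame(rows).set_index("night")


def flag_sleep_days(
    scores: Mapping[date, float] | pd.Series,
    config: ThresholdConfig | None = None,
) -> list[DeviationRecord]:
    """Flag nights whose SDP score strictly exceeds the threshold.

    Identical contract to :func:`dna_monitor.wadi.flag_days`; the default
    configuration is a fixed threshold at :data:`DEFAULT_SDP_THRESHOLD`.
    """
    if config is None:
        config = ThresholdConfig(mode="fixed", fixed_value=DEFAULT_SDP_THRESHOLD)
    if isinstance(scores, pd.Series):
        scores = {d: float(v) for d, v in scores.items()}
    return flag_days(scores, config)
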