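"""Synthetic CASAS-style smart home with ground truth and anomaly injection.

The simulator emulates the behavioral structure the scoring assumes: a
resident with a configurable daytime routine (per-activity mean daily
durations with log-normal day-to-day variation), a nightly sleep session
with wrapped-normal onset on the 24 h clock, normally distributed sleep
period length, and a Poisson number of night-time interruptions rendered as
``Bed_Toilet_Transition`` intervals that carve short wake gaps out of the
Sleep label, exactly as CASAS annotations represent a toilet trip.

Generation is two-stage: first a per-day *plan* of sampled parameters, then
a deterministic rendering of plans into labeled begin/end event pairs.
Anomaly injection rewrites the plans of the targeted days and re-renders, so
all untouched days are byte-identical in the output log, and a sidecar
ground-truth table records what was injected where.

Supported anomaly kinds (the deviation classes the scores should catch):

- ``onset_shift``   — sleep begins ``magnitude`` hours later;
- ``short_sleep``   — sleep period shortened by ``magnitude`` seconds;
- ``fragmentation`` — interruption count forced to ``magnitude``;
- ``routine_swap``  — daytime durations rotated among activities
  (disorganized routine; magnitude = rotation distance, default 1);
- ``night_appliance`` — ``magnitude`` seconds of stove use at 02:30.

It does not simulate raw sensor physics (PIR re-fire patterns, temperature
traces); events exist only as interval begin/end annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .event_io import ActivityInterval, EventStream, SensorEvent, assign_day, NOON_ANCHOR

__all__ = [
    "RoutineSpec",
    "Anomaly",
    "AnomalyPlan",
    "SimulatedHome",
    "ANOMALY_KINDS",
    "DEFAULT_ACTIVITY_MEANS",
    "simulate_days",
    "inject_anomalies",
]

#: Mean daily seconds per daytime activity for an older adult with a
#: structured routine (~8.7 h of labeled daytime activity; sleep is modeled
#: separately).
DEFAULT_ACTIVITY_MEANS: dict[str, float] = {
    "Personal_Hygiene": 2400.0,
    "Cook_Breakfast": 1800.0,
    "Eat_Breakfast": 1200.0,
    "Relax": 7200.0,
    "Cook_Lunch": 1500.0,
    "Eat_Lunch": 1200.0,
    "Work": 5400.0,
    "Cook_Dinner": 2400.0,
    "Eat_Dinner": 1800.0,
    "Watch_TV": 6300.0,
}

ANOMALY_KINDS = {
    "onset_shift",
    "short_sleep",
    "fragmentation",
    "routine_swap",
    "night_appliance",
}

_SLEEP = "Sleep"
_BTT = "Bed_Toilet_Transition"
_STOVE_ACTIVITY = "Cook"

#: Minutes between consecutive daytime activities in the rendered schedule.
_SCHEDULE_GAP_S = 600.0
_MIN_SLEEP_S = 600.0


@dataclass(frozen=True)
class RoutineSpec:
    """Baseline behavioral routine of the simulated resident.

    Defaults describe a regular sleeper: lights out 23:00 +/- 30 min
    (circular), 8 h +/- 30 min in bed, one toilet trip per night on average,
    each costing 5 minutes of sleep, and ~20% day-to-day variation in
    daytime activity durations.
    """

    activity_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MEANS)
    )
    activity_cv: float = 0.2
    onset_mean_h: float = 23.0
    onset_sd_h: float = 0.5
    duration_mean_s: float = 28800.0
    duration_sd_s: float = 1800.0
    interruption_rate: float = 1.0
    interruption_gap_s: float = 300.0
    wake_time_h: float = 8.0
    start_date: date = date(2016, 12, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.activity_means:
            raise ValueError("at least one daytime activity is required")
        for a, m in self.activity_means.items():
            if m <= 0:
                raise ValueError(f"mean duration for {a!r} must be > 0")
        for name in ("activity_cv", "onset_sd_h", "duration_sd_s", "interruption_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_mean_s <= 0:
            raise ValueError("duration_mean_s must be > 0")
        if self.interruption_gap_s <= 0:
            raise ValueError("interruption_gap_s must be > 0")

    def replace(self, **kwargs) -> "RoutineSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Anomaly:
    """One injected perturbation: which day, what kind, how large."""

    day: date
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(
                f"unknown anomaly kind {self.kind!r}; known: {sorted(ANOMALY_KINDS)}"
            )
        if self.magnitude < 0:
            raise ValueError("anomaly magnitude must be >= 0")


AnomalyPlan = Sequence[Anomaly]


@dataclass
class _DayPlan:
    """Sampled parameters for one simulated day (mutable for injection)."""

    day: date
    activity_durations: dict[str, float]
    onset_raw_h: float  # hours since this day's midnight; may exceed 24
    sleep_period_s: float
    n_interruptions: int
    extras: list[tuple[str, float, float]] = field(default_factory=list)
    # extras: (activity, start hours since this day's midnight, duration s)


@dataclass
class SimulatedHome:
    """A simulated event log plus every ground-truth table behind it."""

    spec: RoutineSpec
    plans: list[_DayPlan]
    anomalies: pd.DataFrame

    @property
    def days(self) -> list[date]:
        return [p.day for p in self.plans]

    def truth_intervals(self) -> list[ActivityInterval]:
        intervals: list[ActivityInterval] = []
        for plan in self.plans:
            intervals.extend(_render_day(self.spec, plan))
        intervals.sort(key=lambda iv: (iv.start, iv.activity))
        return intervals

    def sleep_truth(self) -> pd.DataFrame:
        """Per-night ground truth: onset clock hours, sleep seconds, I."""
        rows = []
        for plan in self.plans:
            gap_total = plan.n_interruptions * self.spec.interruption_gap_s
            rows.append(
                {
                    "night": plan.day,
                    "onset_hours": plan.onset_raw_h % 24.0,
                    "sleep_seconds": max(plan.sleep_period_s - gap_total, _MIN_SLEEP_S),
                    "interruptions": plan.n_interruptions,
                }
            )
        return pd.DataFrame(rows).set_index("night")

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "day": iv.source_day,
                "activity": iv.activity,
                "start": iv.start,
                "end": iv.end,
                "duration_s": iv.duration_s,
            }
            for iv in self.truth_intervals()
        ]
        return pd.DataFrame(rows)

    def to_stream(self) -> EventStream:
        events: list[SensorEvent] = []
        sensors = _sensor_map(self.spec)
        for iv in self.truth_intervals():
            sensor = sensors[iv.activity]
            events.append(SensorEvent(iv.start, sensor, "ON", iv.activity, "begin"))
            events.append(SensorEvent(iv.end, sensor, "OFF", iv.activity, "end"))
        events.sort(key=lambda e: (e.timestamp, e.sensor_id, e.marker or ""))
        return EventStream(events=events, provenance=f"synthetic(seed={self.spec.seed})")


def _sensor_map(spec: RoutineSpec) -> dict[str, str]:
    labels = sorted(set(spec.activity_means) | {_SLEEP, _BTT, _STOVE_ACTIVITY})
    return {label: f"M{i + 1:03d}" for i, label in enumerate(labels)}


def _lognormal_duration(rng: np.random.Generator, mean: float, cv: float) -> float:
    # parametrized so that E[X] = mean and CV[X] = cv
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


def _sample_day(spec: RoutineSpec, day: date, rng: np.random.Generator) -> _DayPlan:
    durations = {
        a: max(60.0, round(_lognormal_duration(rng, m, spec.activity_cv)))
        for a, m in spec.activity_means.items()
    }
    onset = float(rng.normal(spec.onset_mean_h, spec.onset_sd_h)) if spec.onset_sd_h else spec.onset_mean_h
    # normalize to [12, 36) hours past this day's midnight: clock times before
    # noon mean "after midnight", i.e. the following morning, so the night is
    # always noon-anchored to its own day
    onset = onset % 24.0
    if onset < 12.0:
        onset += 24.0
    period = float(rng.normal(spec.duration_mean_s, spec.duration_sd_s)) if spec.duration_sd_s else spec.duration_mean_s
    period = max(round(period), _MIN_SLEEP_S)
    k = int(rng.poisson(spec.interruption_rate)) if spec.interruption_rate > 0 else 0
    # keep at least a minimal sleep total after carving out the wake gaps
    k_max = int(max(period - _MIN_SLEEP_S, 0.0) // spec.interruption_gap_s)
    return _DayPlan(
        day=day,
        activity_durations=durations,
        onset_raw_h=round(onset, 4),
        sleep_period_s=period,
        n_interruptions=min(k, k_max),
    )


def _render_day(spec: RoutineSpec, plan: _DayPlan) -> list[ActivityInterval]:
    """Deterministically turn a day plan into labeled intervals.

    Daytime activities run back to back from the wake time with a fixed
    10-minute gap.  The sleep period starts at the (possibly wrapped) onset
    and its interruptions sit at evenly spaced cut points, each opening a
    ``interruption_gap_s`` wake gap labeled as a bed-toilet transition.
    """
    intervals: list[ActivityInterval] = []
    midnight = datetime.combine(plan.day, time(0, 0))

    cursor = midnight + timedelta(hours=spec.wake_time_h)
    for activity, dur in plan.activity_durations.items():
        end = cursor + timedelta(seconds=dur)
        intervals.append(
            ActivityInterval(activity=activity, start=cursor, end=end, source_day=plan.day)
        )
        cursor = end + timedelta(seconds=_SCHEDULE_GAP_S)

    t0 = midnight + timedelta(hours=plan.onset_raw_h)
    t1 = t0 + timedelta(seconds=plan.sleep_period_s)
    k = plan.n_interruptions
    gap = timedelta(seconds=spec.interruption_gap_s)
    cuts = [t0 + (t1 - t0) * ((i + 1) / (k + 1)) for i in range(k)]
    seg_start = t0
    night = assign_day(t0, NOON_ANCHOR)
    for cut in cuts:
        if cut > seg_start:
            intervals.append(
                ActivityInterval(_SLEEP, seg_start, cut, source_day=night)
            )
        intervals.append(ActivityInterval(_BTT, cut, cut + gap, source_day=night))
        seg_start = cut + gap
    if t1 > seg_start:
        intervals.append(ActivityInterval(_SLEEP, seg_start, t1, source_day=night))

    for activity, start_h, dur in plan.extras:
        start = midnight + timedelta(hours=start_h)
        intervals.append(
            ActivityInterval(
                activity=activity,
                start=start,
                end=start + timedelta(seconds=dur),
                source_day=assign_day(start, NOON_ANCHOR),
            )
        )
    return intervals


def simulate_days(
    spec: RoutineSpec, n_days: int, seed: int | None = None
) -> SimulatedHome:
    """Simulate ``n_days`` of routine behavior from the spec's distributions.

    The same spec and seed always produce a byte-identical event log
    (``seed=None`` uses ``spec.seed``).  ``n_days = 0`` yields an empty
    stream.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    plans = [
        _sample_day(spec, spec.start_date + timedelta(days=i), rng)
        for i in range(n_days)
    ]
    anomalies = pd.DataFrame(columns=["day", "kind", "magnitude"])
    return SimulatedHome(spec=spec, plans=plans, anomalies=anomalies)


def inject_anomalies(home: SimulatedHome, plan: AnomalyPlan) -> SimulatedHome:
    """Apply an anomaly plan, returning a new home with perturbed days.

    Every anomaly day must exist in the simulation.  Days not named in the
    plan keep their exact sampled parameters, so their rendered event lines
    are byte-identical to the unperturbed home's.  The returned home's
    ``anomalies`` table is the injection ground truth.
    """
    by_day = {p.day: p for p in home.plans}
    for anomaly in plan:
        if anomaly.day not in by_day:
            raise ValueError(f"anomaly day {anomaly.day} not in simulation")

    new_plans = {
        p.day: _DayPlan(
            day=p.day,
            activity_durations=dict(p.activity_durations),
            onset_raw_h=p.onset_raw_h,
            sleep_period_s=p.sleep_period_s,
            n_interruptions=p.n_interruptions,
            extras=list(p.extras),
        )
        for p in home.plans
    }
    for anomaly in plan:
        target = new_plans[anomaly.day]
        if anomaly.kind == "onset_shift":
            target.onset_raw_h = round(target.onset_raw_h + anomaly.magnitude, 4) % 48.0
        elif anomaly.kind == "short_sleep":
            target.sleep_period_s = max(
                target.sleep_period_s - anomaly.magnitude, _MIN_SLEEP_S
            )
        elif anomaly.kind == "fragmentation":
            k = int(anomaly.magnitude)
            k_max = int(
                max(target.sleep_period_s - _MIN_SLEEP_S, 0.0)
                // home.spec.interruption_gap_s
            )
            target.n_interruptions = min(k, k_max)
        elif anomaly.kind == "routine_swap":
            shift = max(1, int(anomaly.magnitude))
            acts = list(target.activity_durations)
            durs = list(target.activity_durations.values())
            rotated = durs[shift:] + durs[:shift]
            target.activity_durations = dict(zip(acts, rotated))
        elif anomaly.kind == "night_appliance":
            target.extras.append((_STOVE_ACTIVITY, 26.5, float(anomaly.magnitude)))
        else:  # pragma: no cover - guarded by Anomaly.__post_init__
            raise ValueError(f"unknown anomaly kind {anomaly.kind!r}")

    truth = pd.DataFrame(
        [
            {"day": a.day, "kind": a.kind, "magnitude": a.magnitude}
            for a in plan
        ],
        columns=["day", "kind", "magnitude"],
    )
    return SimulatedHome(
        spec=home.spec,
        plans=[new_plans[p.day] for p in home.plans],
        anomalies=truth,
    )
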