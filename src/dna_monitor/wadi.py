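"""Weighted Activity Deviation Index (WADI) and threshold-based day flagging.

WADI scores how far one day's activity time budget sits from a reference
routine::

    WADI = sum_i  w_i * |A_i - R_i|

where A_i and R_i are the day's and the reference's proportion of time spent
on activity i, and w_i >= 0 is the importance weight of that activity
(deviations in sleep or hygiene typically matter more than deviations in
leisure).  A score of 0 means the day matches the routine exactly on every
weighted activity; with weights summing to 1 the score is bounded by 1.
Absolute deviations penalize over- and under-performance symmetrically.

Days are flagged as anomalous when their score strictly exceeds a threshold,
either a fixed value or a dynamic cutoff mean + alpha * std of the score
history; larger alpha flags fewer days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity_profile import DailyActivityProfile, ReferenceRoutine

__all__ = [
    "WeightScheme",
    "WeightValidationReport",
    "ThresholdConfig",
    "DeviationRecord",
    "compute_wadi",
    "validate_weights",
    "dynamic_threshold",
    "flag_days",
    "score_days",
    "records_to_frame",
]

_SUM_TOL = 1e-9


@dataclass
class WeightScheme:
    """Per-activity importance weights w_i (non-negative)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for activity, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {activity!r}: {w}")

    @property
    def total(self) -> float:
        return sum(self.weights.values())


@dataclass
class WeightValidationReport:
    ok: bool
    total: float
    messages: list[str] = field(default_factory=list)


@dataclass
class ThresholdConfig:
    """How to turn a score series into per-day anomaly flags.

    ``fixed`` mode compares every day to ``fixed_value``.  ``dynamic`` mode
    uses mean + alpha * population-std of the score history: of the whole
    series by default, or of a trailing window of ``window`` scores (ending
    at and including the current day) when ``window`` is set.
    """

    mode: Literal["fixed", "dynamic"] = "fixed"
    fixed_value: float = 0.02
    alpha: float = 2.0
    window: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dynamic"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_value < 0:
            raise ValueError("fixed threshold must be >= 0")
        if self.mode == "dynamic" and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.window is not None and self.window < 2:
            raise ValueError("rolling window needs at least 2 scores")


@dataclass(frozen=True)
class DeviationRecord:
    """One day's score, the threshold it was compared to, and the flag."""

    day: date
    score: float
    threshold: float
    flagged: bool


def compute_wadi(
    profile: DailyActivityProfile | Mapping[str, float],
    reference: ReferenceRoutine | Mapping[str, float],
    weights: WeightScheme | Mapping[str, float],
) -> float:
    """Evaluate the weighted sum of absolute proportion deviations.

    The activity set is the union of the day's and the reference's
    activities; a proportion absent on either side counts as 0, so an
    activity dropped entirely from the routine is still penalized.  An
    activity in the union with no weight gets weight 0 with a warning.
    """
    a = profile.proportions if isinstance(profile, DailyActivityProfile) else dict(profile)
    if a is None:
        raise ValueError("profile has no proportions; normalize it first")
    r = reference.proportions if isinstance(reference, ReferenceRoutine) else dict(reference)
    w = weights.weights if isinstance(weights, WeightScheme) else dict(weights)
    for activity, wi in w.items():
        if wi < 0:
            raise ValueError(f"negative weight for {activity!r}: {wi}")

    union = set(a) | set(r)
    unweighted = union - set(w)
    if unweighted:
        warnings.warn(
            f"activities without weights treated as weight 0: {sorted(unweighted)}",
            stacklevel=2,
        )
    return float(
        sum(w.get(i, 0.0) * abs(a.get(i, 0.0) - r.get(i, 0.0)) for i in sorted(union))
    )


def validate_weights(
    weights: WeightScheme | Mapping[str, float], strict: bool = True
) -> WeightValidationReport:
    """Check w_i >= 0 and, in strict mode, sum(w) == 1 (within 1e-9).

    Negative weights are an error in both modes.  In lax mode a non-unit sum
    only produces a warning message, which keeps partially-specified weight
    sets (covering just the activities of interest) usable.
    """
    scheme = weights if isinstance(weights, WeightScheme) else WeightScheme(dict(weights))
    total = scheme.total
    messages: list[str] = []
    ok = True
    if abs(total - 1.0) > _SUM_TOL:
        msg = f"weights sum to {total:.6g}, not 1"
        if strict:
            ok = False
            messages.append(msg)
        else:
            messages.append(msg + " (lax mode: proceeding)")
            warnings.warn(msg, stacklevel=2)
    return WeightValidationReport(ok=ok, total=total, messages=messages)


def dynamic_threshold(scores: Sequence[float], alpha: float) -> float:
    """mean(scores) + alpha * population-std(scores).

    The population standard deviation (ddof=0) is used so the threshold of a
    fixed series is reproducible to the bit.  Larger alpha makes flagging
    more conservative; alpha = 0 flags everything above the mean.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError(
            "dynamic threshold needs at least 2 historical scores; "
            "use a fixed threshold instead"
        )
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return float(arr.mean() + alpha * arr.std(ddof=0))


def flag_days(
    scores: Mapping[date, float] | Sequence[tuple[date, float]],
    config: ThresholdConfig,
) -> list[DeviationRecord]:
    """Compare each day's score to its threshold; flag on strict excess.

    Every input day yields one record.  A score exactly equal to the
    threshold is *not* flagged.  In dynamic mode the threshold is computed
    from the full series (default) or from a trailing window per day; days
    whose window has fewer than 2 scores inherit the first full window's
    threshold.
    """
    items = sorted(scores.items() if isinstance(scores, Mapping) else scores)
    if not items:
        raise ValueError("no scores to flag")
    days = [d for d, _ in items]
    values = np.asarray([s for _, s in items], dtype=float)

    if config.mode == "fixed":
        thresholds = np.full(values.shape, float(config.fixed_value))
    else:
        if config.window is None:
            thresholds = np.full(values.shape, dynamic_threshold(values, config.alpha))
        else:
            ser = pd.Series(values)
            roll = ser.rolling(window=config.window, min_periods=2)
            thr = roll.mean() + config.alpha * roll.std(ddof=0)
            thr = thr.bfill()
            thresholds = thr.to_numpy()

    return [
        DeviationRecord(day=d, score=float(s), threshold=float(t), flagged=bool(s > t))
        for d, s, t in zip(days, values, thresholds)
    ]


def score_days(
    profiles: Sequence[DailyActivityProfile],
    reference: ReferenceRoutine,
    weights: WeightScheme | Mapping[str, float],
) -> dict[date, float]:
    """Convenience: WADI for every (normalized) daily profile."""
    return {p.day: compute_wadi(p, reference, weights) for p in profiles}


def records_to_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    """Records as a day-indexed table with score, threshold and flag columns."""
    frame = pd.DataFrame(
        {
            "score": [r.score for r in records],
            "threshold": [r.threshold for r in records],
            "flagged": [r.flagged for r in records],
        },
        index=pd.Index([r.day for r in records], name="day"),
    )
    frame.attrs["flag_fraction"] = float(frame["flagged"].mean()) if len(frame) else 0.0
    return frame
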