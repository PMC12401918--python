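# Methods

## The model

The package scores each day of an annotated smart-home event log against a
personal reference routine, along two independent axes.

**Activity budget (WADI).** Each day's labeled activity durations are
normalized to proportions `A_i` of that day's total labeled time; the
reference routine supplies proportions `R_i` the same way. The Weighted
Activity Deviation Index is

    WADI = Σ_i  w_i · |A_i − R_i|

over the union of the day's and the reference's activity sets (an activity
dropped entirely still contributes `|0 − R_i|`). Weights `w_i ≥ 0` encode
clinical importance — deviations in sleep or hygiene matter more than
deviations in leisure — and in strict mode must sum to 1, which bounds WADI
by 1. Absolute deviations penalize doing more and doing less of an activity
symmetrically, and WADI is symmetric in day and reference. Unlabeled time
(sensor firings with no activity annotation) is excluded from the
denominator of `A_i`: the score compares the *composition* of annotated
behavior, not coverage of the 24-hour day, and annotation coverage varies
between homes for reasons unrelated to the resident.

**Sleep (SDP).** A night is the noon-anchored date on which it began. Each
night contributes an onset clock time `O` (first Sleep interval start),
total sleep `D` (sum of Sleep-labeled seconds), and interruption count `I`
(Bed_Toilet_Transition intervals inside the sleep span, or optionally short
gaps between Sleep intervals). Against a reference `(R_O, R_D, σ_O, σ_D)`:

    SOD = min(|O − R_O|, 24 − |O − R_O|)      hours, in [0, 12]
    SDD = |D − R_D| / 3600                    hours
    SII = I / D_hours                         interruptions per hour
    SCI = max(0, 1 − σ_O/24 − σ_D/R_D)        unitless, in [0, 1]

    SDP = w1·SOD + w2·SDD + w3·SII + w4·(1 − SCI)

Lower SDP is better. The four components carry heterogeneous units (hours,
per-hour, unitless) and are summed as such by design; the weights therefore
double as implicit unit conversions, and users comparing residents should
keep one weight set fixed. Defaults are equal (0.25 each).

Onset statistics are circular: `R_O` is the circular mean of onsets on the
24 h clock and `σ_O` the circular standard deviation (`scipy.stats.circstd`,
i.e. `sqrt(−2 ln R̄)` mapped to hours). A naive arithmetic mean of clock
hours would place the average of 23:30 and 00:30 at noon. `σ_O` is clamped
at 12 h — the circular standard deviation is unbounded as onsets approach
uniformity, but beyond half the period onset carries no structure and SCI
has already bottomed out.

**Flagging.** A day/night is anomalous when its score *strictly* exceeds a
threshold; ties are not flagged. Thresholds are either fixed (defaults:
0.02 for WADI, 0.4 for SDP — 0.4 being the boundary of the "disrupted"
band, with stable sleepers typically below 0.2) or dynamic:

    threshold = mean(history) + α · std(history)

using the population standard deviation (ddof = 0) so a given series always
yields the bit-identical threshold. The history is the whole score series
by default, or a trailing window (ending at the current day, minimum two
scores, earliest days inheriting the first full window's threshold) when a
window length is configured. Larger α flags fewer days; the flagged set at
α₂ > α₁ is always a subset of the flagged set at α₁. Default α = 2.

**Supporting analyses.** Days flagged by both scores (set intersection)
carry more signal than either alone; per-night counts of chosen sensors or
labels inside a night window (default 22:00–06:00, half-open, wrapping
midnight) screen for e.g. excessive bathroom visits; nights on which a
target activity (typically stove use) accumulates more than a cutoff of
in-window seconds are flagged and paired with that night's sleep duration,
with a Spearman rank correlation reported as a purely descriptive
statistic — no causal claim is computed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| activity weights `w_i` | uniform over observed activities | clinical importance per activity; strict mode requires Σw = 1 |
| WADI fixed threshold | 0.02 | score units; a 2% weighted compositional shift |
| SDP weights `w1..w4` | 0.25 each | relative emphasis of onset / duration / interruption / consistency terms |
| SDP fixed threshold | 0.4 | boundary of the disrupted-sleep band |
| dynamic α | 2.0 | conservativeness of mean + α·std flagging |
| night window | 22:00–06:00 half-open | definition of "night" for counts and episodes |
| appliance cutoff | 1000 s | in-window seconds above which a night's usage is flagged |
| baseline window | all days | reference from all days, or `first:k` for an individual baseline |

## Day and night anchoring

Daytime aggregation splits at midnight and assigns an interval wholly to
the calendar date containing its start (a documented splitting alternative
exists behind `pair_activity_intervals`'s anchor argument). Sleep uses a
noon anchor: an interval starting before 12:00 belongs to the previous
date's night, so a 23:00–07:00 session is one unit attributed to the
evening's date. This is the standard actigraphy convention.

## The reference routine

`R_i` is computed by pooled-mean normalization: the across-day mean seconds
of each activity, divided by the sum of those means. This guarantees
Σ R_i = 1 exactly, which the deviation sum requires of two comparable
distributions; activities absent on a day contribute zero seconds to that
day's term. The alternative (mean of each day's own proportions) weights
all days equally regardless of how much labeled time they contain and is
available via `method="mean_of_proportions"`; the two coincide when every
day has the same total labeled time.

## The synthetic home

The simulator emulates the behavioral structure the scores assume, with
defaults describing a regular older adult: a fixed roster of daytime
activities with log-normal day-to-day duration variation (means totalling
~8.7 h, cv 0.2; log-normal for positivity), sleep onset 23:00 ± 0.5 h as a
wrapped normal on the 24 h clock, an 8 h ± 30 min sleep period (normal,
floored at 10 min), and a Poisson(1) nightly number of interruptions. Each
interruption is rendered the way CASAS annotations represent a toilet
trip — the Sleep label ends, a 300 s `Bed_Toilet_Transition` interval
occupies the wake gap, and Sleep resumes — so interruptions reduce labeled
sleep time. The 300 s gap matches the span of a bed-toilet transition
annotation; interruption cut points sit at evenly spaced fractions of the
sleep period, keeping rendering a deterministic function of the sampled
per-day parameters.

Generation is two-stage (sample per-day parameter plans, then render plans
into begin/end event pairs), which is what makes anomaly injection clean:
an injected anomaly rewrites only the targeted days' plans, so every other
day's rendered lines are byte-identical and the injection ground truth is
exact. Five anomaly kinds cover the deviation classes of interest: onset
shift (hours), shortened sleep (seconds), fragmentation (forced
interruption count), routine disorganization (rotating the day's activity
durations), and night-time appliance use (stove seconds at 02:30).

What the simulator does **not** emulate: raw sensor physics (PIR re-fires,
temperature traces), unannotated events beyond the interval markers,
annotation errors, multi-resident interleaving, or weekday/weekend
structure. Passing tests therefore demonstrate that the scoring recovers
behavioral deviations *given faithful annotations*, not robustness to
recognition noise in real deployments.

## Numerical choices

- Population (ddof = 0) standard deviations throughout (dynamic threshold,
  σ_D), for bit-stable reproducibility.
- Strict `>` for all flag comparisons; ties are never flagged.
- Circular onset statistics via `scipy.stats.circmean`/`circstd` with
  period 24; σ_O clamped at 12 h.
- Zero-labeled-time days raise a dedicated error and are excluded from
  scoring rather than silently scored as empty distributions.
- A night with zero sleep duration has no defined SII and is excluded and
  reported rather than scored.
- Dynamic thresholding refuses series shorter than 2 and directs the caller
  to fixed mode.
- Log-normal sampling is parametrized by (mean, cv) with
  `σ² = ln(1 + cv²)`, `μ = ln(mean) − σ²/2`, so the configured mean is the
  distribution mean exactly; cv = 0 short-circuits to the constant mean.
- Simulated onsets are normalized into [12 h, 36 h) past the day's
  midnight, so an after-midnight onset renders on the following morning and
  every night noon-anchors to its own day.

## Known limitations

- The SDP sum mixes units; scores are comparable within a fixed weight
  choice, not across weightings.
- Dynamic thresholding with a global history is retrospective: a handful of
  extreme days inflates the standard deviation and can mask moderate
  anomalies of a different kind in the same series (a 6 h onset shift can
  hide a fragmented night). Screening for heterogeneous anomaly severities
  is better served by per-metric thresholds or a trailing window.
- Activity labels are taken verbatim; multi-resident homes where the same
  label is produced by different residents are not disambiguated.
- SCI depends only on reference spreads, so against a fixed reference it is
  constant across nights and acts as a per-resident offset in SDP.
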