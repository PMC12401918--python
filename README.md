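# dna-monitor

Behavioral-anomaly scoring for annotated smart-home event logs, aimed at
researchers studying passive, ambient-sensor monitoring of older adults
living alone — where gradual drift in daily routine and sleep is an early
behavioral signal of cognitive decline.

Given a CASAS-dialect event log (whitespace-delimited timestamped sensor
events, optionally annotated with activity labels and `begin`/`end`
markers), the package computes two per-day scores against a personal
reference routine:

- **WADI** (Weighted Activity Deviation Index) over daily activity
  proportions:

  ```
  WADI = Σᵢ wᵢ · |Aᵢ − Rᵢ|
  ```

  where `Aᵢ` is the fraction of the day's labeled time spent on activity
  *i*, `Rᵢ` the same fraction in the reference routine, and `wᵢ ≥ 0` the
  activity's importance weight (Σwᵢ = 1 in strict mode). WADI = 0 means
  the day matches the routine exactly.

- **SDP** (Sleep Deviation Patterns) over four nightly metrics — onset
  deviation `SOD = min(|O − R_O|, 24 − |O − R_O|)` on the 24 h circle,
  duration deviation `SDD = |D − R_D|/3600`, interruption index
  `SII = I / D_hours`, and consistency
  `SCI = max(0, 1 − σ_O/24 − σ_D/R_D)`:

  ```
  SDP = w₁·SOD + w₂·SDD + w₃·SII + w₄·(1 − SCI)
  ```

  Lower is better; stable sleepers typically score below 0.2, disrupted
  ones above 0.4.

Days are flagged when a score strictly exceeds a fixed threshold (0.02 for
WADI, 0.4 for SDP by default) or a dynamic one, `mean + α·std` of the
score history. Supporting analyses cover the overlap of WADI- and
SDP-flagged days, night-time activity counts (e.g. bathroom visits between
22:00 and 06:00), and nights with prolonged appliance use paired with that
night's sleep duration. A synthetic CASAS-style home simulator with
ground-truth anomaly injection (onset shifts, shortened or fragmented
sleep, routine disorganization, night-time stove use) makes the whole
pipeline testable without any external dataset.

## Worked example

```python
from dna_monitor import (Anomaly, RoutineSpec, ThresholdConfig, compute_wadi,
                         extract_sleep_sessions, flag_sleep_days,
                         inject_anomalies, pair_activity_intervals,
                         score_sleep_sessions, simulate_days)

# WADI for one day against a reference, three weighted activities
weights   = {"Sleep": 0.25, "Personal_Hygiene": 0.10, "Cook_Breakfast": 0.08}
reference = {"Sleep": 0.30, "Personal_Hygiene": 0.10, "Cook_Breakfast": 0.05}
daily     = {"Sleep": 0.25, "Personal_Hygiene": 0.12, "Cook_Breakfast": 0.10}
print(f"WADI = {compute_wadi(daily, reference, weights):.4f}")

# simulate a perfectly regular resident, delay one night's sleep by 5 h,
# and let the dynamic threshold find it
spec = RoutineSpec(onset_sd_h=0.0, duration_sd_s=0.0,
                   activity_cv=0.0, interruption_rate=0.0)
home = simulate_days(spec, 14, seed=1)
home = inject_anomalies(home, [Anomaly(home.days[6], "onset_shift", 5.0)])
sessions = extract_sleep_sessions(pair_activity_intervals(home.to_stream()))
table = score_sleep_sessions(sessions)
records = flag_sleep_days(table["sdp"], ThresholdConfig("dynamic", alpha=1.0))
print(table.loc[[r.day for r in records if r.flagged],
                ["onset_hours", "sod", "sdp"]])
```

prints

```
WADI = 0.0185
            onset_hours       sod       sdp
night
2016-12-07          4.0  4.722218  1.193355
```

The WADI of 0.0185 decomposes as 0.25·0.05 + 0.10·0.02 + 0.08·0.05 —
the sleep shortfall dominates because sleep carries the largest weight.
In the simulation, the one shifted night (sleep began at 04:00 instead of
23:00) is the only night flagged: its onset sits 4.72 circular hours from
the reference onset (the reference itself is dragged slightly toward the
outlier), giving an SDP of 1.19 against nights scoring ≈ 0.1.

## Command line

```sh
dna simulate --days 30 --seed 1 --out home.log          # synthetic log
dna wadi --log home.log --threshold dynamic:2            # per-day table
dna sdp  --log home.log --threshold fixed:0.4            # per-night table
dna report --log home.log --out report.json              # combined report
```

Weights and simulator settings come from a flat YAML/JSON config
(`--config`); `dna simulate --anomalies plan.yaml` injects a ground-truthed
anomaly plan.

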