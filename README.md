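# actipair

Validation tooling for paired-device physical-activity measurement: compare
a consumer smartphone accelerometer worn at the waist against a
research-grade accelerometer, minute by minute, the way epidemiologists
validate a new instrument against a reference.

Smartphone accelerometry is attractive for population studies — people
already carry the device — but before phone-derived activity measures can
replace a purpose-built monitor, two questions must be answered on the same
participants wearing both instruments:

1. **Usability** — how easily does each device yield a *valid assessment*
   (≥ 3 days with ≥ 10 hours of wear)? Phones get switched off, run out of
   battery, and sit on desks; the reference device mostly just records.
2. **Validity** — when both devices are worn, do their vertical-axis
   measures, activity durations and energy-expenditure estimates agree?

`actipair` implements the full analysis pipeline for such a study, plus a
synthetic paired-cohort generator with exact ground truth so every stage is
testable without any data download.

## What the pipeline computes

* **Epoching** — raw tri-axial samples are summarized to 1-minute epochs
  (calendar minutes, half-open). The phone's vertical-axis measure is the
  per-minute mean absolute deviation from the minute's median vertical
  acceleration (g/min); the reference device reports manufacturer counts/min.
* **Clock alignment** — device clocks disagree by up to a few minutes; the
  integer-minute offset in ±5 min maximizing the adjusted R² between the two
  vertical-axis series is searched and applied.
* **Wear time** — nonwear is ≥ 40 consecutive recorded minutes of 0 counts
  (reference) or < 0.3 g (phone); usability is summarized per participant
  (days recorded, recorded time, wear fraction, valid days) and compared
  across devices with the Kruskal–Wallis rank-sum test.
* **Energy expenditure** — vertical-axis measures map to metabolic
  equivalents through Freedson-style linear equations,

      reference: METs = 1.439008 + 0.000795 · VT counts/min
      phone:     METs = 1.2907087 + 0.4141791 · VT g/min

  and minutes partition into sedentary [0, 1.5), light [1.5, 3),
  moderate [3, 6) and vigorous [6, ∞) METs. `fit_unit_calibration`
  re-derives the counts-per-g unit link from any aligned pair by OLS
  (heteroscedasticity-robust standard errors).
* **Agreement** — Spearman correlation and adjusted R² for pooled
  vertical-axis minutes; Lin's concordance correlation coefficient
  (CCC = 2·cov(x,y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²), interpretable as
  between-subject variance over total variance) and Bland–Altman analysis
  (mean difference, ±1.96 SD limits of agreement, proportional-bias
  regression of differences on pair means) for per-participant activity
  durations and intensities — at minute level over coinciding time periods,
  and at day level over coinciding valid days as a sensitivity analysis.

## Worked example

```python
import actipair as ap

cfg = ap.CohortConfig(n_participants=6, protocol_days=3, seed=42)
cohort = ap.simulate_cohort(cfg)
result = ap.run_study(ap.manifest_from_cohort(cohort))

mc = result.minute_comparison
s = mc.vt.spearman
print(f"VT: rho={s.rho:.3f} (95% CI {s.ci_low:.3f}-{s.ci_high:.3f}), "
      f"adjR2={mc.vt.adjusted_r2:.3f}, n={mc.vt.n}")
a = mc.active_pct
print(f"active%: CCC={a.ccc.ccc:.3f}, mean diff={a.bland_altman.mean_diff:.2f} pp")
m = mc.mean_met
print(f"mean MET: CCC={m.ccc.ccc:.3f}, mean diff={m.bland_altman.mean_diff:.3f} METs")
```

prints

```
VT: rho=0.954 (95% CI 0.952-0.956), adjR2=0.993, n=11322
active%: CCC=0.975, mean diff=1.05 pp
mean MET: CCC=0.964, mean diff=-0.026 METs
```

Reading: over the 11 322 minutes both devices recorded while worn, the two
vertical-axis measures rank-correlate at 0.954 and a linear regression
explains 99% of the variance — the phone tracks the reference closely at
this (mild) simulated noise level. Per participant, the phone overestimates
the share of active time (≥ 1.5 METs) by about 1 percentage point and
underestimates mean intensity by 0.03 METs; concordance above 0.95 means
less than 5% of the between-participant variability is attributable to the
measurement method. Each participant's injected clock offset is recovered
by the alignment scan (`result.analyzed[i].scan.clock_shift`).

The same analysis runs from the shell:

```bash
actipair simulate --config cohort.yaml --out data/
actipair run --manifest data/manifest.yaml --out results/
```

writing `usability.csv`, `agreement_minute.json`, `agreement_day.json`,
`class_intensity.csv`, Bland–Altman plot tables and a `run.log` of every
exclusion. Subcommands `epoch`, `align`, `wear` and `mets` expose the
individual stages.

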