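# Methods

This note documents the models and procedures `actipair` implements, the
parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions adopted where the design was open.

## Epoch summarization

Raw tri-axial samples are reduced to calendar-minute epochs (half-open
`[t, t+60 s)`). The phone's per-minute vertical-axis intensity is the mean
absolute deviation of vertical acceleration from the minute's median, in g.
The median stands in for the gravity component: it is parameter-free,
insensitive to the device's exact orientation, and yields values near zero
for a motionless device (overnight phone recordings sit below 0.3 g, which
is what the nonwear threshold exploits). The vertical axis is declared in
the reader's dialect configuration (default `y`): for a waist-worn device
orientation is a deployment property, not something inferable from the
signal. Minutes inside the recording span with no samples are coded missing
(`NaN` in memory, `NA` in files), never dropped — downstream wear logic must
distinguish "not recorded" from "zero movement".

The reference device's counts/min are taken as given from its epoch export;
reproducing the manufacturer's band-pass count filter from raw samples is
out of scope.

## Clock alignment

The phone and reference clocks are set independently and can disagree by a
few minutes. All 11 integer offsets in ±5 minutes are scored by the
adjusted R², `1 − (1 − R²)(n−1)/(n−2)`, of the simple regression between
the two vertical-axis series over jointly recorded minutes, and the argmax
is applied to the phone series. Choices made here:

* **Granularity** is whole minutes — epochs are the finest shared unit and
  sub-minute search would require re-epoching.
* **Ties** resolve to the smallest absolute offset, then the negative one:
  deterministic, and prefers "no shift".
* **One offset per participant**, estimated over all coinciding data; clock
  drift within a deployment week is negligible relative to 1-minute epochs.
* Because per-offset sample sizes differ slightly (edges of the overlap),
  the adjusted rather than raw R² is compared across offsets.
* Every candidate must have ≥ 30 jointly recorded minutes, otherwise the
  scan aborts with per-offset overlap counts; a winner on the window edge
  is flagged, since the true shift may lie outside the search range.

Adjusted R² is invariant to affine rescaling of either series, so the
chosen offset does not depend on units.

## Wear and usability

Nonwear is a maximal run of at least 40 consecutive recorded minutes at
near-zero intensity: exactly 0 counts/min for the reference device, below
0.3 g/min for the phone (a threshold calibrated on overnight recordings).
A single supra-threshold minute breaks a run; missing minutes break runs
too and remain `not_recorded`. No interruption tolerance is applied — the
rule is plain consecutive minutes. Lowering the minimum run can only add
nonwear minutes (monotonicity), and the three states always partition the
covered minutes; both properties are under test.

Usability is summarized per participant-device: days recorded (≥ 1 recorded
minute, midnight-to-midnight local days), recorded and worn minutes,
recorded and worn hours per recorded day, percent of recorded time worn,
valid days and the valid-assessment flag. A **valid day** has ≥ 10 hours
(600 minutes) of *wearing* time by default; a configuration switch
(`valid_day_basis="recorded"`) selects the recorded-time variant of the
rule, since both readings circulate in practice. A **valid assessment**
needs ≥ 3 valid days. Metrics are compared across devices with the
tie-corrected Kruskal–Wallis rank-sum test (any number of groups ≥ 2); when
every value ties across groups the statistic degenerates and `H = 0,
p = 1` is reported rather than raised.

## Energy expenditure and intensity classes

Vertical-axis intensities map to METs by linear equations:
`1.439008 + 0.000795·counts/min` for the reference device and
`1.2907087 + 0.4141791·g/min` for the phone. The phone coefficients are the
composition of a fitted counts-per-g unit calibration with the reference
equation; `fit_unit_calibration` re-derives such a calibration from any
aligned pair so study-specific coefficients can replace the shipped ones.
The fit is OLS with **HC1 heteroscedasticity-robust standard errors**:
accelerometer noise is predominantly multiplicative, so residual variance
grows with signal level and classical standard errors understate slope
uncertainty.

Intensity classes use lower-inclusive boundaries — sedentary [0, 1.5),
light [1.5, 3), moderate [3, 6), vigorous [6, ∞) METs — and "active" means
≥ 1.5 METs. The inclusive convention at 1.5 is fixed by the active-time
definition and extended to 3 and 6 for consistency; a strict-inequality
variant of the active boundary is exposed (`active_inclusive=False`) for
sensitivity analysis.

Both linear equations floor at their intercept: an epoch of zero movement
predicts 1.439 METs on one device and 1.291 on the other. This is a real
limitation of count-based MET prediction at rest, and it is why the two
devices' *mean intensity* can disagree even with perfectly matched
hardware — the within-class comparison (reference-assigned classes, Welch
two-sided t-test on minute METs; the test choice is ours) quantifies where
such disagreement lives.

## Agreement battery

* **Minute level** ("coinciding time periods"): comparisons restrict to
  minutes both devices recorded *and* both were worn. The vertical-axis
  association (Spearman with average ranks, Fisher-z CI with variance
  1/(n−3); adjusted R²) pools all participants' joint minutes — the huge-n
  confidence interval this yields is the intended granularity. Activity
  summaries (active-time %, per-class duration %, mean METs) are computed
  per participant and compared with Lin's CCC and Bland–Altman analysis.
* **Day level** ("coinciding valid days"): per-day class durations
  (min/day) on days valid on *both* devices, without restricting to
  coinciding minutes. Comparing the two levels shows whether wearing-time
  discrepancies, rather than measurement differences, drive disagreement.

CCC is computed with n-denominator moments; its confidence interval uses
Lin's asymptotic variance of the Fisher z-transform. When the two compared
vectors are identical constants the formula is 0/0; the comparison batteries
report the limiting value 1 (perfect agreement), while the bare `ccc()`
raises, since agreement between two constant unequal sequences is a
different, well-defined case (CCC 0 < c < 1) and silent coercion would mask
errors. The Bland–Altman abscissa is the pair mean (x + y)/2 — the standard
choice; regressing differences on half the *difference* would be
degenerate. Proportional bias is declared when the 95% CI of the slope of
differences on means excludes zero. The mean difference carries a t-based
CI; limits of agreement are mean ± 1.96 SD of the differences.

## Synthetic cohorts

The generator emulates the two-device deployment that motivates the
package: by default 36 participants × 5 days, clock offsets uniform on
±5 minutes, ~7.5 h of shared overnight off-body time plus ~2 daytime
nonwear episodes per day (putting realized wear near 55–60% of recorded
time), a daily phone-charging episode, ~10% of phone days and ~4% of
reference days lost entirely, and occasional phone recording gaps. Activity
is piecewise-constant bouts (mean 150/45/15 light/moderate/vigorous minutes
per day) whose within-bout MET jitter is clipped to the bout's class
interval, so per-class daily minutes are *exact* ground truth rather than a
target. The true MET trajectory is inverted through each device's equation
to its native unit, floored at zero, then device noise is applied
(multiplicative + additive Gaussian; reference zeros stay exactly zero, as
a real count accumulator's do).

Sedentary waking minutes mix two kinds: "quiet movement" minutes with METs
drawn just above both equation intercepts (1.44–1.495) — a waist sensor
sees incidental trunk motion, so worn sedentary time produces nonzero
counts and is not mistaken for nonwear — and completely "still" minutes
(default probability 0.25) that read zero on both instruments. Runs of 40
consecutive still minutes while worn are vanishingly rare (0.75 fidget
probability per minute), so detected nonwear tracks true off-body time.

`CohortConfig.noiseless()` defines the exact-identity configuration: no
noise, no offsets, no recording losses, and no still minutes — the last
because still minutes sit below both intercepts where the linear maps are
not invertible, and the identity this configuration supports is exact
invertibility. It is a fixture configuration, not a study condition.

What the synthetic data do **not** emulate: realistic raw waveform
biomechanics (raw streams are per-minute sinusoids scaled to reproduce the
g/min trajectory), manufacturer count filtering, posture, clock drift
within a deployment, and correlated day-to-day behaviour. Passing tests
therefore demonstrate the pipeline's correctness and statistical behaviour
under the stated generative model, not device-specific accuracy on real
recordings.

## Numerical conventions and degenerate inputs

* Statistics drop incomplete pairs pairwise; minimum n is 3 (4 for
  Spearman), below which an undefined-statistic error is raised rather than
  a NaN returned.
* Zero-variance regressors raise; a constant *response* in the alignment
  scan scores adjusted R² = 1 (the regression reproduces it exactly).
* Empty activity-minute sets yield a flagged empty summary, not an error;
  participants with zero joint minutes are excluded with a logged reason,
  and enrolled = analyzed + excluded always holds.
* All simulation randomness flows from one `SeedSequence` spawned per
  participant, making cohorts bit-reproducible under a fixed seed.

## Problem sizes used in tests

The default test suite simulates small cohorts (≤ 8 participants × ≤ 3
days) for speed; the alignment-recovery property is checked over 100
single-participant 3-day seeds, calibration recovery at n = 1000 minutes,
and bias detection at n = 500 paired days — sizes at which the asymptotic
confidence intervals involved are already well behaved. The acceptance
script's cohort check runs the full 36 × 5 study design.

## Known limitations

* Regressing on a noisy observed regressor attenuates an OLS slope
  (regression dilution); the unit-calibration recovery guarantees hold for
  response-side noise, which is how the calibration was designed to be fit
  (reference counts on phone g over jointly worn minutes, with the phone
  measure treated as the design variable).
* The Spearman CI uses the generic Fisher-z variance 1/(n−3), adequate at
  the pooled-minute sample sizes involved but approximate for small n.
* Day boundaries are local midnight; shift workers' "days" are not modelled.
* The within-class intensity comparison treats minutes as independent,
  ignoring within-participant correlation; with the pooled sample sizes
  involved its p-values are indicative, not exact.
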