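# Methods

This note documents the statistical and modelling choices behind
alarmlab: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Event-log model

All times are minutes on a phase-local axis; every interval — alarm
episodes and monitoring coverage alike — is half-open `[start, end)`,
so abutting intervals neither overlap nor leave gaps and duration sums
are unambiguous.  The study phase (pre/post) is a dataset-level label,
not inferred from timestamps: the intended use is fixed observation
windows, not continuous streams.  Each logged alarm row is treated as
one alarm episode; whether a monitor fragments a long physiologic
episode into several logged alarms around silences is
vendor-dependent, and the model deliberately takes the log at face
value.

Arterial pressure is modelled as three parameters (systolic,
diastolic, mean) with independent limits but is *reported* as a single
"Arterial" group, reflecting how such tables are conventionally
printed.  SpO2 alarms carry only a low-limit direction (units rarely
configure a high SpO2 limit).  PVC-per-minute alarms are admitted by
the data model but excluded from every standard reporting group: on
units where the PVC alarm is inaudible by default it contributes
essentially no alert burden.

## Alert-trigger engine

Both trigger rules evaluate a trailing window anchored at the silence
press: `(t − W, t]` for the silence count (so the triggering press
itself counts — five presses six minutes apart trigger at the fifth)
and `[t − W, t]` for the time-in-alarm fraction.  The fraction rule is
strict (`> f`, not `≥`), so a window sitting exactly at the threshold
does not fire.  When both rules fire at one press, the silence-count
rule is reported — the count is the more interpretable trigger and a
precedence had to be chosen.

Two behaviours of the deployed product are unknowable from the outside
and are exposed as configuration:

* **Refractory behaviour.**  By default every qualifying press
  re-alerts (ten presses a minute apart yield alerts at presses 5–10).
  `refractory_minutes` suppresses repeat alerts for a key within the
  given spacing, for sensitivity analyses.
* **Silenced vs total alarm time.**  The fraction rule measures *all*
  violation time in the window, not only unsilenced time.

The engine costs `O((n_silences + n_alarms) log n)` via per-key sorted
indexes; tests verify alert-for-alert equality with a full-rescan
reference implementation on random streams.

## Exposure weighting and rates

The reporting denominator is the bed hour.  Overall exposure is the
per-bed union of the standard-of-care channels (HR, RR, SpO2) so that
simultaneous channels never triple-count an hour; arterial rows use the
union of the three arterial channels, because arterial-line coverage is
much sparser and phase-specific.  Post-phase totals are weighted to
pre-phase exposure with half-away-from-zero integer rounding; percent
reductions are computed from unrounded rates and displayed at one
decimal, rates at two.

One reproduction caveat, recorded here deliberately: when the weighted
cells of a published duration table are recomputed from the printed
integer totals and hours, two cells land one unit below the printed
value (7167.43 vs a printed 7168; 3216.39 vs 3217) — consistent with
the original weighting having used unrounded internal monitoring hours.
The package's tests therefore assert weighted duration cells to within
one count.  Likewise the printed per-bed-hour means are bootstrap
means, which can differ from the deterministic ratio in the last
printed digit (one cell in sixteen does).

## Bed-hour discretization

Histograms and the bootstrap resampling unit both need a partition of
monitored time into bed hours.  Hours are clock-aligned
(`[60k, 60(k+1))` on the phase axis); a partial hour counts as exposure
only when at least 30 minutes of it are covered.  Alarm *counts*
attribute an episode to the hour containing its start; alarm *minutes*
are split across the hours an episode overlaps.  Rolling (rather than
clock-aligned) windows were the alternative; clock alignment keeps
every alarm in exactly one bin and matches how monitoring systems
export hourly tallies.

## Bootstrap inference

The resampling unit is the per-bed-hour value (count or minutes),
pooled across beds within a phase.  This makes "mean alarms per bed
hour" the literal estimand and is the simplest defensible unit; a
hierarchical bootstrap by bed (or patient) would respect within-bed
correlation and is noted as an extension, not implemented.  Intervals
are percentile intervals (2.5/97.5), not BCa; the two-sample p-value
resamples each group independently and doubles the smaller tail of the
resampled mean difference, clipped to `[2/B, 1]` so a p-value is never
reported below the Monte-Carlo resolution.  Defaults: `B = 10,000`,
95 % level, an explicit integer seed recorded in every report.
Calibration tests check ~95 % CI coverage and ~5 % null rejection over
1,000 replications at n = 100.  Because published bootstrap SDs and
CIs depend on an unknown resampling unit, they are reproduced
qualitatively, never cell-for-cell.

## Survey and patient comparisons

Likert items are dichotomized (default endorsement levels {4, 5}) into
phase × endorsement fourfold tables; out-of-scale responses are
excluded and tallied.  The chi-square is the uncorrected Pearson form
(`n(ad − bc)²/((a+b)(c+d)(a+c)(b+d))`, df = 1): the uncorrected form
reproduces the published p-values (0.027, 0.026, 0.043) to three
decimals, which a Yates-corrected test does not.  Per-item denominators
vary (66/44 for most items, 43 post-phase for the time-consumed item)
and are encoded per item.  The rank-sum test uses exact enumeration of
group assignments (valid under ties via midranks) when the pooled n is
at most 20, otherwise the normal approximation with tie correction.
Ages of 90+ are top-coded to a single category, so age is compared on
the coded ordinal scale and no mean age is computed.

## Synthetic generator

Per bed and parameter group, alarm starts follow a homogeneous Poisson
process over the monitoring interval and durations are exponential
(truncated at the phase end).  Defaults are the observed pre-phase
figures of a 56-bed medical ICU over two months: rates ≈ 1.00 (HR),
1.46 (RR), 1.10 (SpO2) per bed hour, 5.36 per arterial-line hour;
mean durations ≈ 2.85, 0.15, 0.31, 0.36 min; pooled high-priority rate
≈ 1.06 per bed hour; total exposure ≈ 36,545 bed hours with ≈ 5 % of
it arterial.  Each episode is silenced with probability 0.8 at a
uniform time inside it, 30 % of presses remote — plausible unit
behaviour, chosen once; neither is observable in published aggregates.

A gamma bed-frailty multiplier (shape 0.7, mean 1) is on by default:
pure Poisson arrivals cannot produce the observed heavy per-bed-hour
tails (single bed-hours with 30+ alarms), while bed-level
overdispersion — some patients alarm almost continuously — does.
Tests that verify parameter *recovery* switch frailty off so the
configured rate is the exact Poisson mean.

The post phase adds the intervention's causal path: streams are
simulated sequentially, every silence is evaluated against the trigger
rules on the stream's own history, and a *displayed* alert leads, with
probability `adjust_probability`, to the bed-parameter's subsequent
rate being multiplied by `rate_multiplier`, once per bed-parameter.
Defaults (0.5 and 0.85) are free parameters — no published study
measures how often nurses act on such alerts — set to a regime whose
reductions are of the observed order (roughly 5–15 % for affected
groups).  With certain adjustment and multiplier *m*, the post/pre rate
ratio converges into `[m, 1)`: the reduction begins only after the
first alert on each stream.

What the generator does **not** emulate, so passing tests say nothing
about: seasonal case-mix drift (e.g. winter respiratory admissions),
patient turnover within a phase, acuity-linked alarm rates, clustered
silencing behaviour, alarm validity (true/false), and any coupling
between parameters on one patient.  Conclusions about real units
require real logs through the same pipeline.

## Problem sizes and numerics

Tests and the acceptance script run the generator at desk scale
(hundreds to a few thousand bed-hours, 5–40 beds), chosen so every
stage — including 10,000-iteration bootstraps — completes in seconds
while Poisson counts are large enough for 3-standard-error recovery
checks.  All randomness flows from named integer seeds through
`numpy.random.Generator`; independent streams are spawned via
`SeedSequence`, so datasets, bootstrap results and whole report bundles
are bit-reproducible.  Degenerate inputs are defined, not accidental:
zero exposure or a zero baseline rate yields NaN cells in reports (and
explicit errors in the scalar functions); constant samples give a
zero-width bootstrap interval, p = 1 in the rank-sum test, and an error
in the Anderson–Darling fit.
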