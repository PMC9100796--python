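# Methods

## The measurement problem

A day is exhaustively partitioned into sleep, sedentary behaviour (SB),
light physical activity (LPA) and moderate-to-vigorous physical activity
(MVPA); the four durations are co-dependent and close to 1440 min. Two
instruments estimate this composition for a usual week:

* a **recall questionnaire** covering sleep (bed/rise times, sleep latency,
  wake after sleep onset, napping) and domain-specific SB and physical
  activity (occupational, commuting, other non-occupational), with
  clock-time, visual-analogue (VAS), yes/no and day/duration item types;
* a **thigh-worn inclinometer** worn 24 h/day for a week, exporting an
  events file of sitting/lying, standing and stepping bouts with cadence,
  accompanied by a nightly sleep diary (intended sleep onset, wake time,
  nap minutes).

The package evaluates the questionnaire twice: against itself a week apart
(test-retest reliability) and against the device (convergent validity).

## Questionnaire scoring

Per occasion and participant:

* `sleep = TIB − latency − WASO + nap_days × nap_duration / 7`, with time in
  bed (TIB) the bed→rise clock span computed modulo 24 h (rise ≤ bed means
  next-day rise). `latency + WASO ≥ TIB` is a scoring error and invalidates
  the record.
* `SB = workplace_span × VAS_occ × workdays/7 + commute × VAS_commute +
  other_SB`. Occupational quantities are weekly and averaged by
  `× workdays/7`; commuting and "other" items are treated as already-daily.
  This day-weighting convention is not uniquely determined by the
  instrument's public description and is documented field-by-field so a
  different instrument export can be remapped.
* `MVPA = [flag] × days × duration/7 (occupational) + commute_MVPA +
  days × duration/7 (other)`; the occupational yes/no flag gates its domain
  to zero.
* `LPA = 1440 − sleep − SB − MVPA`. A negative remainder (over-reporting)
  flags the record invalid rather than truncating, so agreement analyses can
  exclude it and closure diagnostics stay meaningful.

VAS proportions are stored on a 0.01 grid, matching the resolution of a
"none of the time … all of the time" slider.

## Device processing

Days run **noon-to-noon** so each night belongs to one day. Per day:

1. **Time-in-bed candidate**: the longest run of sitting/lying events
   mergeable across interruptions (upright events or wear gaps) of at most
   15 min in total; ties break to the earliest start. Found by a two-pointer
   sweep over sitting/lying runs.
2. **Sleep fusion**. An *upright burst* is ≥ 60 s cumulative
   standing/stepping within any 5-min span (both numbers are config knobs —
   the notion must separate a genuine rise from brief bathroom-break noise,
   and no published definition exists). Onset: the diary value stands unless
   a burst occurs in the 20 min after it, in which case onset is the first
   sitting/lying event after the last in-window burst. Offset: the diary
   wake stands unless it falls after the first burst that follows > 1 h of
   contiguous sitting/lying, in which case the offset is the end of the last
   sitting/lying event before that burst. A diary tie (wake exactly at the
   burst) resolves to the diary. Missing diary: the candidate window is
   used, with the source recorded.
3. **Waking classification**: sitting/lying → SB; standing and stepping
   below the cadence cut-point → LPA; stepping at ≥ 100 steps/min → MVPA.
   The cut-point approximates the 3 MET boundary for stepping cadence and is
   pluggable. Events straddling a sleep boundary are split at it.
4. **Naps**: diary nap minutes move from SB to sleep (total unchanged). If
   the nap exceeds that day's SB, only the available minutes transfer and
   the day is flagged (`nap_exceeds_sb`) — the choice of clamping rather
   than failing keeps an obviously inconsistent diary from destroying an
   otherwise valid day.
5. **Non-wear**: gaps in the event stream. A day is valid with wear
   > 20 h (non-wear < 4 h). On valid days non-wear is reallocated
   proportionally over SB/LPA/MVPA only — sleep is never scaled — restoring
   closure to 1440.
6. **Weekly averaging**: arithmetic mean over valid days; participants with
   fewer than 5 valid days are excluded (flagged, not dropped silently).

Internal arithmetic is in seconds; minutes appear in outputs, rounded to one
decimal only at the reporting layer.

## Agreement statistics

With k = 2 measurements per participant and the two-way participants ×
occasions ANOVA mean squares (MS_R rows, MS_C columns, MS_E error):

* `ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E)` — consistency;
* `ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))` —
  absolute agreement.

95% CIs follow the single-measure two-way F-based formulas (McGraw & Wong
1996): an exact F pivot for ICC(C,1) and the Satterthwaite-df approximation
for ICC(A,1). Spearman's ρ uses mid-ranks for ties and a percentile
bootstrap CI over paired case resamples (B = 2000 default; the seed is a
required argument wherever the bootstrap runs). Bland–Altman differences are
questionnaire minus comparator; the mean difference takes a t-based CI (a
normal-based CI would differ only in the third decimal at n > 100, but the
t choice is recorded because either is defensible); the limits of agreement
are mean ± 1.96 SD with CIs from `SE(LoA) = SD·√(3/n)` and t multipliers.
Proportional bias is the OLS slope of differences on pair means with its
t-test p — the standard Bland–Altman regression, since a slope "β" alone
does not pin down the design matrix. Bonett's sample-size formula is

`n = ⌈ 8 z²_{1−α/2} (1−ρ₀)² (1+(k−1)ρ₀)² / (k(k−1) w²) + 1 ⌉`,

which gives n = 101 for ρ₀ = 0.70, half-width 0.10, k = 2, α = 0.05.

## The synthetic cohort

Latent weekly compositions are drawn by sampling sleep, SB and MVPA from
normals truncated at zero and closing LPA (redrawing when any part would be
non-positive). The normal locations are analytically adjusted so the
*truncated* means equal the configured population means — without this, a
behaviour near the zero boundary (MVPA especially) would inflate by several
min/day. Defaults:

| parameter | default | rationale |
|---|---|---|
| population mean (sleep, SB, LPA, MVPA) | 443, 547, 419, 31 min/day | typical working-adult questionnaire magnitudes; LPA closes the simplex |
| between-subject SD (sleep, SB, MVPA) | 50, 130, 25 min | yields observed questionnaire SDs near 60/165/35 min once occasion error is added |
| test-retest error SD (sleep, SB, MVPA) | 40, 100, 15 min | puts expected test-retest ICCs near 0.55–0.65, the range such questionnaires attain; the MVPA value accounts for the variance lost to the zero boundary |
| device bias (sleep, SB, MVPA) | −1, +96.5, +39.1 min/day | the device sees essentially all sitting and brisk stepping; recall misses much of both, and the compensating LPA deficit follows by closure |
| device day-level error SD | 25 min | day-to-day measurement noise on top of the workday/non-workday pattern |
| non-wear | exponential gap, mean 0.25 h/day, minimum 5 min | occasional shower/swim removals |
| naps | p = 0.15/day, 30 min | extra daytime sitting the diary reports as a nap |
| diary jitter SD | 10 min | diary-vs-true onset/wake error |
| bedtime upright burst | p = 0.1, 10 min after onset, 2 min upright | the "got up again" pattern the onset fusion rule exists for |
| workday SB shift | 60 min LPA→SB on workdays | workday/non-workday contrast; weekly mean preserved exactly |

Questionnaire responses are built by *inverting* the scoring rules around a
target composition (latent + occasion noise): clock items are quantised to
whole minutes and VAS items to 0.01, and the continuous duration items
(WASO, "other" SB/MVPA) absorb the quantisation residuals, so scoring
reproduces the target to floating-point precision. Device weeks tile each
noon-to-noon day exactly: one night sitting/lying block, waking bouts whose
class totals equal the day's measured composition, naps as extra daytime
sitting, and non-wear carved *proportionally* from the waking totals so that
the downstream proportional reallocation is its exact inverse.

Per-participant RNG streams derive from `(cohort seed, participant index)`
via `SeedSequence`, so cohorts are reproducible and order-independent.

### What the generator does and does not emulate

It emulates: between-subject compositional variation, occasion noise,
device bias and day noise, diary error, naps, non-wear, workday structure,
bedtime bursts, and attrition (missing second occasions; short device
weeks). It does **not** emulate: raw accelerations (generation starts at
the event level, where processing also starts), posture-misclassification
by the device, correlated questionnaire biases (social desirability),
night-shift sleep timing (a `shift_work` flag exists but shifts are not
scheduled), or multi-sleep days. Passing tests therefore demonstrate that
the *pipeline arithmetic and statistics* behave as specified under known
truth — not that any real questionnaire is valid.

Two asymmetries of the fusion rules are visible in simulated output and
worth knowing about: a diary that reports waking *earlier* than the device
is believed (shortening sleep), while one reporting *later* is overridden —
so symmetric diary jitter produces a small negative sleep bias (~10 min/day
at 10-min jitter) and a corresponding SB surplus. This mirrors how the
rules would behave on real data.

## Numerical and testing choices

* Closure asserted to 1e-6 min; round trips to 1 min/day.
* The ICC implementations are checked against a plain-loop sums-of-squares
  ANOVA oracle (1000 random datasets, 1e-10) and cross-checked against an
  independent library implementation; the fusion rules against a
  1-s-sampling brute-force scanner and six hand-traced night fixtures.
* Calibration: 500 replicate cohorts of n = 114 at a true ICC of 0.65
  (error SD set analytically from the between-SD) give the mean ICC(C,1)
  estimate and empirical 95% CI coverage; both are recomputed by
  `scripts/acceptance.py`. Problem sizes (126-participant default cohort,
  500 replicates, 1000 oracle datasets) keep any single check under half a
  minute on one CPU while leaving Monte-Carlo error well inside the
  tolerances asserted.
* Ties: mid-ranks in ρ; earliest start for equal time-in-bed spans; diary
  wins the offset tie.

## Known limitations

* The questionnaire item schema is the minimal closure of the published
  scoring rules, not the full 32-item instrument; unlisted items (sleep
  quality, napping frequency as outcomes) are out of scope.
* The cadence→MET mapping is a single cut-point; a published regression
  could be plugged into `ProcessingConfig.cadence_cutpoint`'s place but is
  not bundled.
* Compositional data-analysis methods (log-ratio ICCs etc.) are
  deliberately not implemented; all statistics operate per behaviour on the
  raw minutes scale.
* Split-shift (multi-sleep) days are processed as a single main sleep
  window; the secondary sleep lands in SB and is then only partially
  recovered via the nap pathway.
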