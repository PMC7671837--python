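# Methods

`dokit` re-implements, as a tested toolkit, the measurement and
decision-making machinery of a just-in-time adaptive intervention (JITAI)
for reducing sedentary behaviour in cardiac-rehabilitation patients: a
hip-accelerometer outcome pipeline, GPS-derived behavioural scoring, a
rule-based "Do" dispatch engine, a synthetic free-living cohort generator,
and the trial-design statistics a feasibility study produces. This note
records the models, rules, defaults, and design choices, and what the
synthetic data can and cannot establish.

## Accelerometer outcome pipeline (`dokit.accel`)

The pipeline starts from 15-second triaxial epoch counts as exported by
device software (the raw 30 Hz to counts conversion is vendor-proprietary
and out of scope; the simulator emits epoch counts directly).

**Counts per minute.** Per-epoch vector magnitude is `sqrt(ax²+ay²+az²)`;
a minute's VM cpm is the sum of its up-to-4 epoch VMs. Minutes covered by
fewer than 4 epochs are scaled by `4/epochs_present` to keep cpm units.
Summing per-epoch VMs (rather than taking the VM of summed axes) was
chosen because it preserves cpm additivity; the difference is negligible
for the magnitudes involved.

**Nonwear.** A maximal run of **more than 60** consecutive zero-cpm
minutes (i.e. ≥ 61) is nonwear, with *no allowance*: a single nonzero
epoch splits the run. Runs of exactly 60 zeros remain wear. Choi- or
Troiano-style alternatives are deliberately not implemented.

**Intensity.** Triaxial vector-magnitude cut-points: sedentary < 150 cpm,
light 150–2689 cpm, MVPA ≥ 2690 cpm. Boundaries are closed on the side
the band names them (150 is light, 2690 is MVPA).

**Bouts and breaks.** A sedentary bout is a run of sedentary wear minutes
of at least 10 min with no drop time (any non-sedentary minute ends the
run); a positive `drop_time` is available but not default. "Break" has no
universal definition in daily summaries; we count a break when a bout is
followed, before day end and before the next sedentary minute, by at
least one *wear* non-sedentary minute. This yields `breaks = bouts − 1`
whenever the day's last bout runs into nonwear or midnight, reproducing
the familiar paired bout/break daily counts; `count_trailing=True`
switches to `breaks = bouts`.

**Screening.** Days are local midnight-to-midnight with no DST handling.
A day is valid with ≥ 600 min (10 h) wear; a participant's summary
requires ≥ 4 valid days and averages over *all* valid days even when more
than 7 exist. Steps are carried through from the device stream, not
inferred from counts.

## GPS mobility features (`dokit.gps`)

"Place" is operationalised with standard mobility-mining parameters, all
configurable: anchor-based stay-point detection (radius 100 m, minimum
dwell 10 min), places merged at 150 m, great-circle distances. A place is
*new* on the first date it is ever seen; *uncommon* places are those with
at most 2 visits in the trailing 28 days. Daily distance sums
consecutive-fix hops, discarding hops implying > 200 km/h (GPS teleports;
the threshold retains train travel). Route dissimilarity is the
normalised Levenshtein distance between today's ordered place-id sequence
and the closest baseline day's sequence; timing shift is the mean
absolute difference of position-matched visit start times, scaled by 12 h
and clamped to [0, 1]. Intraday data coverage is the fraction of 48
half-hour slots containing a GPS fix or a wear minute — coarse enough to
be robust to duty-cycled GPS.

## Scoring and dispatch (`dokit.engine`, `dokit.catalog`)

Three variables are scored daily, each the equal-weight mean of its
rescaled subcomponents:

| variable | subcomponents |
|---|---|
| physical activity | steps/day; active (non-sedentary wear) minutes |
| social opportunity | new places visited; dwell time in them |
| variety | uncommon places; distance; route dissimilarity; timing shift |

Rescaling is anchored to the participant's **baseline week** (the 7 days
preceding the program): each subcomponent maps linearly onto 0–10 between
the minimum and maximum recorded that week, saturating at 0 below the
minimum and 10 above the maximum. Days failing the > 60% coverage gate
are excluded from the min/max; at least 3 passing days are required. A
degenerate bound (min = max) maps every value to a neutral 5 — the
rescaling rule is only defined for min < max, and neutrality avoids
manufacturing "low" days from a constant signal.

Faces cut the 0–10 range into thirds: sad below 10/3, neutral below 20/3,
smiley above; the 14-day overview renders low-coverage days blank.

**Dispatch rule.** A data-driven Do for variable *v* goes out on day *t*
iff (a) *v* scored below the low threshold (default 10/3, the sad band)
on each of the last 3 days, (b) each of those days passed the coverage
gate, (c) fewer than 3 Do's have been sent this ISO week (Mon–Sun), and
(d) an unused data-driven Do targeting *v* remains. Ties between
qualifying variables go to the lowest 3-day mean, then the fixed order
pa < social < variety. A dispatched Do resets its variable's streak
(3 fresh low days are needed), so a variable can trigger at most twice
per week. Do selection walks a per-participant seeded shuffle of the
catalog, so sequences are individualised but reproducible; no Do is ever
repeated for a participant.

**Catalog.** 89 entries — 14 core, 75 data-driven (25 per variable) — of
which 30 target sedentary behaviour / physical activity. Texts are
synthetic placeholders (the original catalog is unpublished); the shape,
kinds, targets and flags are what downstream logic consumes. Core Do's
activate from ordinal 1–5 intake answers via per-entry rules; three
generic entries activate at low thresholds (≥ 2, i.e. any occurrence of
the habit) while habit-specific entries require ≥ 4 ("often"). The
pipeline schedules core Do's on Mondays and Thursdays while the activated
queue lasts, under the same shared 3-per-week cap; the delivered volume
of 14–19 Do's over 6 weeks (≈ 2.3–3.2/week against a cap of 3) implies
core delivery above one per week.

Adherence is the percentage of dispatched Do's marked completed,
reported to one decimal with half-up rounding.

## Synthetic cohort (`dokit.simulate`)

The generator emulates a sedentary cardiac-rehabilitation population on
the study's timeline: participants start on a Monday; days 0–6 are the
baseline/profiling week (also the baseline accelerometer wear), days 7–48
the six dispatch weeks, with 7-day accelerometer assessments at weeks 0,
6 and 16 (112 days total).

**Population.** Daily wear is uniform on 840–1316 min (≈ 18 h mean);
baseline sitting is a uniform fraction 0.41–0.91 of wear. Bounded,
light-tailed (platykurtic) between-participant spreads are used
deliberately: at n = 20 the sampling noise of a Cohen's d is dominated by
the SD estimate, whose CV scales with population kurtosis, and a bounded
population keeps replicate-to-replicate d estimates stable enough for
effect-recovery checks to be informative. Resulting cohort baseline
magnitudes (n = 50): ≈ 737 min/day sitting, ≈ 7 800 steps/day, ≈ 70
min/day MVPA, ≈ 270 min/day light activity, ≈ 1 070 min/day wear —
matching the population the toolkit targets (11–12 h/day sitting, ≈ 18 h
wear).

**Slumps.** Behaviour is autocorrelated through two-state Markov chains:
one shared "off week" chain (enter 0.13/exit 0.22 per day: ~37%
occupancy, mean ~4.5 days) that depresses all three variables at once,
plus an independent chain per variable (enter 0.12/exit 0.22). In a
slump, sitting rises by 7% of base, novel-place arrivals drop from
0.9/day to 0.1/day, uncommon places from 1.0 to 0.08/day, distance from
~18 km to ~4 km, and route dissimilarity/timing shift collapse toward
routine. This multi-day structure is what makes 3-consecutive-low-day
triggers fire at a realistic rate; with independent days the engine would
sit idle. Under these defaults simulated participants receive 14–19 Do's
over the 6 dispatch weeks in ≥ 80% of cases, concentrated at 16–18 —
consistent with near-saturated dispatch under a 3/week cap.

**Day construction.** Given a day's target sitting/light/MVPA totals, the
schedule is built as alternating sedentary and active runs: lognormal
sedentary run lengths (σ = 1.1, participant-level mean ≈ 12.5 min,
scaled with the day's sitting target) partitioned to sum *exactly* to the
targets, so generative truth is well defined. Sedentary minutes draw cpm
from a zero-inflated (30% zeros) exponential below 150; light and MVPA
minutes draw truncated exponentials inside their bands. Minute cpm is
split across 4 epochs by Dirichlet weights and decomposed onto three axes
by near-unit direction cosines, rounded to integer counts. Steps accrue
per active minute (≈ 88/min MVPA, ≈ 6/min light). Epoch and GPS streams
draw from day-keyed child generators, so daily truth is identical whether
or not streams are materialised.

**Responsiveness and dropout.** Each completed Do (completion probability
0.737, the observed adherence) lowers the target sitting time by
`responsiveness` minutes — default −9.2, sized so a typical program's
~12 completed Do's accumulate to a generative reduction of roughly 107
min/day by week 16, realised as shortened sedentary runs. Follow-up
dropout is missing-at-random: 5% at week 6, 40% at week 16 (matching
19/20 and 12/20 assessed).

**Fidelity modes.** Epoch streams are materialised for the three
assessment weeks (where the study measured ActiGraph outcomes); between
assessments the engine consumes device-reported daily aggregates, as the
deployed system did. Full GPS fixes can be materialised and scored
through `dokit.gps` end to end (`score_from_gps=True`); large replicate
runs score from the generator's daily mobility truth instead, which the
GPS path reproduces up to stay-point/merge granularity.

**What the simulator does not model.** No physiology (heart rate, energy
expenditure), no device noise spectra, no wear-time reactivity, no
seasonal or weekday structure beyond the work itinerary, and no
behaviour-change mechanism other than the linear completed-Do effect. In
particular, reduced sitting is converted into light activity and steps
mechanically, so simulated step-count gains under an effective program
are larger than field data typically show. Passing recovery tests
demonstrates that the *pipeline* is faithful, not that the intervention
works in humans.

## Study-level statistics (`dokit.stats`)

Cohen's d between two timepoints uses the pooled SD
`sqrt((s1² + s2²)/2)` — the unique standard pooling consistent with both
published sedentary-behaviour effect sizes given the outcome table — with
positive d meaning a reduction, reported to two decimals. A-priori sample
size for a two-group two-sided t test iterates the noncentral t
distribution (df = 2n−2, noncentrality d·√(n/2)) to the smallest n
reaching target power, seeded by the normal approximation; statsmodels'
independent solver is used only as a test oracle. Recruitment under
dropout is `ceil(n / (1 − rate))` per group. Feasibility percentages use
half-up rounding, matching every published ratio. Missing follow-ups are
imputed by last observation carried forward at the participant-summary
level (intention-to-treat), never changing a participant's count of
actually-assessed timepoints. Repeated-measures ANOVA/Friedman inference
is out of scope — standard tools exist.

## Numerical and degenerate-input choices

- `rescale` with min = max returns 5; with min > max raises.
- Zero wear minutes give `sb_pct_of_wear = 0` and an invalid day, not NaN.
- `adherence([])` is None (undefined), not 0.
- Empty GPS days yield zero features and no places; fewer than 2 fixes
  yield no stay points.
- Catalog exhaustion for a triggered variable logs a warning and sends
  nothing that day.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; per-participant and per-day child seeds are
  derived, keeping any seed below 2³¹.

## Problem sizes used in the checks

Property checks run at the scale the behaviour stabilises: dispatch
properties on 200 simulated 6-week participants; effect recovery on 200
closed-loop replicates of n = 20 over 16 weeks (with epoch-level
measurement at the three assessment windows) plus null cohorts at n = 50;
oracle equivalences on dozens of random days. The accelerometer oracle
comparisons and boundary enumerations are exhaustive at the scales they
cover.

## Known limitations

- The dispatch engine's "low" threshold, face bands, subcomponent
  weights, and the ISO-week cap window are documented defaults for
  under-specified rules of the original system; all are configurable.
- The break definition and the core-Do schedule are reconstructions (see
  above) — the original system's exact rules are unpublished.
- Simulated GPS uses straight-line transit and fixed fix rates; urban
  canyon effects, signal dropouts and map-matched routes are absent.
- The uncommon-place history starts at day 1 (no pre-study mobility
  history is assumed).
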