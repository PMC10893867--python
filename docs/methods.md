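# Methods

This note documents the scientific and numerical choices behind
`vpabouts`: what the pipeline computes, what the synthetic cohort generator
emulates (and deliberately does not), and the decisions taken where the
underlying method left the design open.

## Epoch model

The unit of analysis is the 5-second epoch of ENMO (Euclidean norm of
triaxial acceleration minus 1 g, negatives truncated to zero before
averaging, in mg) plus a z-axis tilt angle. Intensity classes follow the
children's non-dominant-wrist ENMO cut-points (56.3 / 191.6 / 695.8 mg).
Prose definitions of such cut-points are ambiguous at the boundary values
themselves; this implementation uses half-open, lower-inclusive intervals
(a value equal to a cut-point belongs to the class above it, so 695.8 mg is
VPA). This is a convention, not an inference; it affects only measure-zero
sets of the continuous signal.

The raw-to-epoch converter computes the per-epoch tilt angle as
`atan(z̄ / sqrt(x̄² + ȳ²))` from the per-epoch axis means rather than a
rolling median of raw samples: only 5-second-scale *changes* in angle are
consumed downstream (the strict non-wear rule), so the cheaper estimator is
adequate. All clock arithmetic is naive local time; every rule in the
method is expressed in wall-clock terms, and no DST transition occurs in a
single 8-day assessment in the modelled school year. Auto-calibration and
abnormal-value screening are assumed to have happened upstream: input ENMO
is taken as calibrated.

## Non-wear

Device non-wear algorithms tuned for long removals miss short ones, so
device flags are supplemented by a strict sustained-inactivity rule:
maximal runs of at least 30 minutes in which every successive 5-s angle
change stays below 2°. The run length is evaluated on the full record and
the resulting flag is then clipped to the 8:00 AM–10:00 PM crediting
window: the 30-minute criterion describes the physical behaviour (a watch
lying still), while the window describes where non-wear is *credited* —
overnight stillness is sleep, not removal. A run straddling 8:00 AM
therefore counts even though only its post-8:00 portion is flagged. The
union with device flags is monotone: nothing is ever un-flagged.

Imputation fills residual non-wear inside days that survived the validity
rules, at the epoch level: each missing clock slot takes the majority
intensity class observed at the same slot across the subject's other valid
days of the same day type, ties resolving toward the lower-intensity class,
with all valid days as the fallback donor pool. Epoch-level majority rather
than fractional minute averaging was chosen because downstream bout
detection needs a concrete class per epoch; the majority preserves expected
minutes for dominant behaviours. Donors are always the subject's own days,
never other subjects'. Donor epochs must be genuinely worn (imputed epochs
never donate), which makes the step idempotent and order-free. Imputed
epochs are marked and participate in every subsequent minute and bout
statistic. A config hook (`substitute_reported_sport`) can overwrite a
non-wear interval that coincides with a reported sport session with a
template class sequence from a similar observed activity.

## Day types, sleep and validity

Five day types (school with a valid PE class, school without, weekend,
holiday, absence) and two segments (out-of-bed to 2:00 PM, 2:00 PM to bed).
A scheduled PE class that fails its validity rule (≥ 1 min non-wear, or
neither ≥ 3 MVPA minutes nor ≤ 30 sedentary minutes) demotes the day to
"school day without PE" rather than discarding it: the day type is defined
by the presence of a *valid* PE class, and the day itself may still be
valid. The PE rule's grammar is read as: non-wear < 1 min is a hard
data-quality condition AND (MVPA ≥ 3 min OR sedentary ≤ 30 min) is the
activity evidence.

Wake and bed times come from a deliberately simple heuristic — the longest
run of sedentary epochs with a rolling 5-minute angle SD below 5° whose
(clipped) start falls after 19:00; bed is that clipped start, wake is where
the run ends the next morning (capped at noon). Candidate runs must last at
least one hour; failing that, configured defaults (23:00 / 7:30) are used
with a warning. A sleep-log CSV always takes precedence, which keeps the
pipeline faithful when truth is known. On synthetic cohorts the heuristic
recovers wake and bed to within ±2.5 minutes; the test suite asserts the
weaker ±10 minutes on ≥ 95 % of days.

Validity rules (day ≥ 20 recorded-and-worn hours with ≤ 2 h non-wear in
8:00–22:00; awake ≤ 2 h; segments ≤ 1 h each; school time ≥ 4 recorded
hours with ≤ 1 h non-wear; assessment ≥ 4 valid weekly days covering all
three analyzed types with valid segments) gate everything: no bout, minute
or compliance statistic is ever computed from an invalid day or attached to
an excluded subject. "Recorded" time equals epochs present and flagged
worn.

## Bout construction

The sex-specific thresholds are canonically the epoch counts per 60-minute
window — 120 for boys (1/6) and 90 for girls (1/8), i.e. 10.0 and 7.5 VPA
minutes per hour. The rounded percentage forms (16.7 %) are presentation
only: 16.7 % of 720 epochs would be 120.24 and force 121.

A window qualifies when its VPA count reaches the threshold; an epoch is in
a bout when covered by at least one qualifying window; bouts are maximal
runs of in-bout epochs. This construction is deterministic, order-free and
oracle-checkable; the bout itself is *not* required to satisfy the density
constraint over its full extent. One consequence worth stating explicitly:
a fully saturated 60-minute VPA run produces a bout that extends beyond the
run, because partially overlapping windows also reach the threshold (for a
girl, up to 52.5 minutes on each side); the VPA content of the bout is
unaffected. Windows are clipped to the day's wake–bed interval and never
cross midnight: the day is the analysis unit, and segments are defined
within awake time. Imputed epochs count toward window contents, since
imputation precedes all reported statistics. `brute_force_bouts`
re-implements the contract by explicit per-window scanning and serves as
the independent oracle; equality is asserted on 1000 random days in the
test suite. A bout overlapping 2:00 PM credits both daily segments.
Out-of-school bout minutes are the bout durations intersected with the
After-2-PM segment on school days and the whole day on weekends.

## Aggregation and compliance

Duplicate weekdays (an 8-day assessment always repeats one weekday) are
averaged within (weekday, day type) pairs — two same-weekday days of
different final type are not "identical days" — and binary bout flags
average to proportions, so a slot whose duplicates disagree contributes a
fractional day-with-bout. Weekly values combine the school-day and
weekend-day means with weights 5/7 and 2/7; the same weighting builds
out-of-school values from After-2-PM school segments and whole weekend
days. Compliance is the fractional generalization of "at least one bout on
at least 3 of 7 valid weekly days": the sum of slot bout proportions over
valid weekly slots, divided by the number of valid slots, must reach 3/7.
This keeps the rule well-defined when valid day counts range from 4 to 9
and is monotone: adding a bout day can never revoke compliance.

Group tests: Shapiro-Wilk at α = 0.05 per group gates the choice between
Student's t and Mann-Whitney U for independent contrasts; Wilcoxon
signed-rank for paired contrasts (p omitted when all differences are tied
at zero); Pearson chi-square without continuity correction for compliance
proportions. Reported organized sport (0–11 h/week) is grouped as 0, 1–2,
≥ 3 h/week and binarized at 3 h/week; non-participants count as 0 h and
subjects missing the questionnaire stay in the accelerometer analyses but
drop out of sport-grouped tables. All internal arithmetic is full
precision; rounding to 1 decimal place happens only at table output.

## Synthetic cohort generator

The generator's defaults define the study conditions under which the test
suite runs. Schedules: at least 8 consecutive days starting on a Monday of
the modelled 2019/20 school year; school 9:00–14:00 with a 30-minute recess
starting uniformly between 11:00 and 12:00; PE (60 min, at 9:00 or 13:00)
on two school weekdays; bed time uniform 21:00–23:00, wake 7:00–8:30 on
school days and 8:00–9:30 otherwise. Contexts are piecewise-constant blocks
(sleep, sedentary, free play, recess, PE class, sport session, transit);
within a block, epoch classes are i.i.d. draws from the context's class
probability vector and ENMO is uniform within the class's cut-point band
(VPA capped at 2000 mg) — the classification is threshold-based, so the
within-class shape is irrelevant to the pipeline. Default VPA shares:
sport sessions 0.35, vigorous PE 0.30 (each PE class is vigorous with
probability 0.5, otherwise emitted as free play), free play 0.03, recess
0.08, transit 0.01, sedentary and sleep 0.

Ground truth marks a 60-minute window as must-detect when its *expected*
VPA density reaches the sex threshold plus a margin (default 0.05 density);
windows inside the margin are may-detect and excluded, which keeps tests
away from the stochastic decision boundary. A subject is expected-compliant
with must-detect intervals on at least 3 of the 7 weekly day slots.
Designed-compliant subjects receive three vigorous sessions on three
distinct weekdays (reported sport ≥ 3 h/week, session length = reported
hours split over the sessions, minimum 60 min); designed-non-compliant
subjects report either no organized sport or sport that is emitted as
low-intensity free play — mirroring the observation that reported
organized sport, especially in girls, often does not reach vigorous
intensity on the wrist. The cohort assigns exactly `round(p·n)` compliant
subjects, so the designed prevalence is a count, not a Bernoulli draw.

Injected non-wear emulates an evening removal (e.g. a shower): per day with
probability 0.15, an episode of 30–60 minutes starting between 19:00 and
19:45, device-flagged only when ≥ 45 minutes so the strict rule has genuine
work on the shorter episodes. Sleep-time tilt angle is smooth (successive
changes < 2°), which is exactly why the strict rule is restricted to
8:00–22:00; the generator reproduces that interplay deliberately, including
the small spurious non-wear credit between a pre-22:00 bed time and 22:00.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: physiologically realistic 40 Hz waveforms,
autocorrelated within-block intensity (real activity is bursty, not
i.i.d.), posture shifts during sleep, seasonal and weather effects,
device miscalibration, and between-subject variation in schedule structure
beyond the parameters above. Recovery results (perfect day-level bout
sensitivity/specificity) hold under margin-separated session densities;
real sessions near the threshold will be detected with error.

## Problem sizes and tolerances

The oracle-equivalence check uses 1000 random synthetic days; recovery and
prevalence checks use a 50-subject cohort (8 days each, ≈ 6.9 M epochs),
chosen as the smallest cohort where the exact binomial 95 % interval of the
designed prevalence is reasonably tight. The prevalence check accepts any
estimate inside that interval: a designed-compliant subject can lose a
session weekday to the non-wear validity gate (the day is then excluded,
and 2 remaining bout slots out of 6 valid slots fall below 3/7), which is
correct pipeline behaviour, not detection error. Moment checks on the
generator use a 3-standard-error tolerance. Sex and compliance mixes are
assigned by exact counts, so small-cohort tests are deterministic given the
seed; per-subject seeds are spawned from a single seed sequence.
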