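# Methods

This note documents the models, parameter choices and limitations of
the `tripsense` pipeline: what the synthetic cohort generator emulates,
how the minute-level features are defined, how the forests are trained
and evaluated, and which design decisions were genuinely open.

## Outcome and data model

The outcome is a five-class minute-level label: `activity_place`
(being at a fixed visited location) or one of four transport modes
(`walk`, `bike`, `public_transport`, `private_motorized`). Ground
truth is a timetable of episodes per participant — half-open minute
spans `[start, end)` that tile the follow-up with no overlaps or
holes. A *trip* is a maximal sequence of transport episodes between
two activity places; each single-mode segment of a trip is a *stage*
(adjacent stages always differ in mode, since a stage is maximal).
Minute indices count from each participant's follow-up start; the
half-open convention avoids double-labelled boundary minutes.

Three raw streams accompany the timetable: GPS fixes (position,
speed, HDOP/VDOP/PDOP, satellites in view and used), 5-second
accelerometer epochs (tri-axial counts and steps, under a standard
and a low-frequency-extension count filter), and RR intervals.

## The synthetic cohort generator

The generator reproduces the *statistical* structure this analysis
needs, not street-level realism (no road network, no real geography;
coordinates are a speed-consistent random walk and are deliberately
not used as predictors).

**Schedules.** Daily trip counts are Poisson with mean
`trips_per_day = 5.1` (median 5 trips/day); stages per trip are
1 + Poisson(0.7) (mean 1.7, about 8.7 stages/day); stage durations are
Gamma(2, ·) with the scale chosen so expected daily transport time
matches `time_on_trips_frac = 0.069` of the 1440-minute day (roughly
100 minutes). Stage durations are clipped to 2–45 minutes. Remaining
minutes are allocated to activity-place episodes around the trips via
a Dirichlet split with a one-minute floor, so every trip is flanked by
activity places. Stage modes are drawn from `mode_mix` (walk 0.45,
public transport 0.25, private motorized 0.22, bike 0.08 — a dense
European city mix where biking is the rare class).

**Sensor signatures.** Each mode has a mean cruising speed with
between-minute (stops, traffic) and within-minute (fix jitter)
variation; log-normal minute-level accelerometer intensity driving
Poisson epoch counts; a step rate (steps are zeroed in sedentary
epochs, since one cannot step without counts); and a heart-rate
elevation over the participant's resting rate. The defaults were fixed
once, during design, so that the classification task is neither
trivial nor hopeless: motorized modes overlap heavily in speed
(public transport 24 ± 14, private motorized 30 ± 16 km/h at the
minute level), biking (13 ± 5.5 km/h, low hip counts, high heart-rate
elevation) borders both walking and the motorized modes, and
activity-place speeds are capped below 1 km/h. Walking is easy by
design (high counts, steps, ~5 km/h) — as it is for real hip-worn
devices. The low-frequency-extension variant adds non-negative
Poisson counts concentrated on near-sedentary epochs, so LFE counts
dominate standard counts epoch-wise.

**GPS degradation in public transport.** Each public-transport stage
is "underground" with probability 0.55; its HDOP/VDOP are inflated
4-fold (PDOP is derived as √(HDOP² + VDOP²)) and satellite counts
collapse, so most underground fixes fail the quality filter and many
underground minutes lose GPS entirely — mirroring how metro travel
disappears from GPS records and making public transport the hardest
class.

**Participant heterogeneity.** Gaussian random effects on resting
heart rate (SD 8 bpm), walking speed (SD 1 km/h) and a log-normal
multiplier on accelerometer counts (SD 0.35 on the log scale). These
are the mechanism behind the split-level bias: a forest that has seen
minutes from a participant partially memorizes that participant's
sensor idiosyncrasies, so minute-level train/test splits look better
than participant-level ones. Setting the SDs to zero shrinks the bias,
which the acceptance suite checks.

**Wear gaps.** All devices come off during a nightly 23:00–07:00 sleep
window (participants in such studies are instructed to remove devices
overnight); during wake, each sensor independently drops whole minutes
(GPS 20 %, accelerometer 10 %, heart-rate patch 45 % — the chest patch
has by far the worst compliance). Only minutes with all three sensors
survive the merge, leaving about a quarter of total follow-up, which
matches the merge attrition seen in real three-sensor deployments.
This extends the plain per-minute Bernoulli dropout model with the
sleep window because without it the merged data volume per day would
be unrealistically high.

**Determinism.** One master seed drives a `SeedSequence` spawn per
participant; identical configs give byte-identical cohorts.

## Feature engineering

* GPS fixes are kept iff HDOP < 6 **and** VDOP < 7 **and** PDOP < 8
  (strict inequalities). Per minute: the seven summary statistics
  (mean, median, sample SD with n−1, min, max, linear-interpolation
  10th/90th percentiles) of speed, elevation, the three DOPs and the
  two satellite counts (49), plus the valid-fix count and the fraction
  of raw fixes passing the filter (51). A minute whose fixes all fail
  the filter counts as GPS-absent.
* Accelerometer, per filter variant: seven statistics of epoch
  vector-magnitude counts and of METs (14), step sum, MVPA-epoch and
  sedentary-epoch counts (17 × 2 variants = 34), plus the seven
  statistics of each axis for the standard variant (21): 55 total.
  METs = 0.000863 · VM(counts/min) + 0.668876, with 5-s epoch counts
  scaled ×12 to counts/min first; kcal/min = METs × 3.5 × weight/200.
  MVPA means METs ≥ 3; sedentary means axis-1 counts < 100 cpm. The
  MET coefficients and both cut-points are conventions from the
  calibration literature, exposed as module constants because
  laboratories differ.
* Heart rate: 12 time-domain HRV measures per minute (mean/median RR,
  SDNN, RMSSD, SDSD, pNN50, CV of RR, mean/SD/min/max HR with
  HR = 60000/RR per beat, and the beat count). Successive differences
  never cross minute or participant boundaries; minutes with fewer
  than 3 intervals get missing variability values. Frequency-domain
  HRV is out of scope — one-minute windows are too short.
* Time: minutes since midnight (0–1439) and a weekend flag.
* Labels: the episode with the largest overlap with the minute wins;
  ties go to the earlier episode. (Simulated timetables are
  minute-aligned, but user-supplied ones may have second-resolution
  boundaries.)
* The merged table keeps only minutes with all three sensors present;
  the catalogue is a fixed, versioned ordering of the 120 names.
  Whether energy expenditure should enter as METs or kcal/min is not
  settled; the epoch derivations emit both, and the minute catalogue
  summarizes METs.

## Models and evaluation

Forests are 100 bagged Gini trees with library defaults (√p features
per split, unlimited depth), fitted by scikit-learn; each tree casts
one hard vote and vote shares are the per-class fractions of trees.
Rows with any missing feature are dropped (and counted) before
training. Two feature sets are supported: `with_hr` (120 predictors)
and `without_hr` (108).

*Naive OOB*: each training minute is voted on only by the trees whose
bootstrap resample excluded it (~37 % of trees on average; the
in-bag/OOB fractions converge to 1 − 1/e and 1/e). *LOOCV*: one
iteration per participant, the forest never seeing the held-out
participant's minutes; per-iteration seeds derive from the master seed
by fixed offsets, all below 2³¹.

The prevalence cut-off correction divides each class's vote share by
its training prevalence before the argmax — equivalent to moving each
class's prediction threshold to its observed proportion — and is
applied only at forest aggregation, never inside tree growing. Ties
break toward the fixed class order (alphabetical). With uniform
prevalence it reduces exactly to the unweighted argmax.

Rates are percentages of correct minutes: overall; overall transport
(true-transport minutes only, exact mode required — the wording could
also mean binary trip-vs-place accuracy, so that is emitted as a
supplementary cell); and per-class recall. Cells with zero denominator
are missing, never zero. Across LOOCV iterations each cell is
summarized as median (2.5th–97.5th percentile), excluding iterations
missing that cell; displayed tables round to integers while CSVs keep
full precision. Variable importance offers both the Gini (mean
impurity decrease) and a per-tree OOB permutation accuracy decrease,
as ensemble forests conventionally report.

## Homogenization

The moving-majority filter is **non-recursive**: every output minute
is the modal *raw* prediction in the window `[t−b, t+b]`, so the
result is independent of processing direction (the recursive in-place
variant would not be; direction invariance is tested). Windows are
truncated at the edges of contiguity blocks — maximal runs of
consecutive minutes — and never span wear gaps or participant
boundaries. A tied window majority keeps the raw centre label;
b = 0 is the identity. Consequences proved in the tests: a run of
length L ≤ b flanked by ≥ b minutes of one other mode is erased
entirely, and under independent flip noise at rate p < ½ inside long
constant segments the expected accuracy at b = 1 follows the exact
3-window enumeration. Whole-segment consensus relabelling is a
non-goal: it needs known trip boundaries, which this standalone
pipeline deliberately does not assume.

## Problem sizes

The package's own experiments run at desk scale, chosen once as part
of the study design: the split-bias and weighting checks use cohorts
of 20 participants × 2 days (≈ 15,000 merged minutes, 20 forests per
run) over three seeds, with heterogeneity on and off; the determinism
check uses 6 participants × 2 days; calibration checks on the
schedule generator use 50–60 participants × 7 days without sensor
streams. Larger cohorts (the generator defaults are 126 participants
× 7 days) run with the same code.

## What passing tests do and do not show

The synthetic generator draws minutes independently given the episode
and participant effects; it has no serial correlation within episodes
beyond the episode's mode and underground flag, no drift or device
failure modes, no map-matched geography, and boundary minutes are
cleanly labelled (real prompted-recall timetables mislabel some
boundary minutes). Passing the directional checks therefore shows the
*pipeline* reproduces the methodological phenomena — split-level
optimism under participant heterogeneity, recall redistribution under
prevalence weighting, gain then over-smoothing under homogenization —
not that the absolute prediction rates on any real cohort would match
the synthetic ones. Absolute rates here are generally higher than on
real data because the synthetic classes are cleaner.

## Known limitations

* Activity-place detection is nearly perfect on synthetic data
  (speeds are capped below walking pace); real GPS drift at indoor
  locations makes that class harder.
* The generator's heart-rate model is stationary within a minute with
  Gaussian beat jitter; real RR series have autonomic trends and
  artefacts that HRV pre-processing normally has to clean.
* `bootstrap_inclusion_fraction` and the OOB machinery assume the
  scikit-learn bootstrap (resample size = training size); forests with
  subsampling would need different expectations.
* No GIS predictors, no hyperparameter tuning, no alternative
  learners: the scope is the forest-plus-post-processing workflow.
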