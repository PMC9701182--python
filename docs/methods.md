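# Methods

This note documents the models implemented in marathonlab, the design
decisions taken where more than one reasonable choice existed, what the
synthetic-data generator does and does not emulate, and the numerical
conventions shared across modules.

## Activity representation

Raw trackers sample cumulative (distance, time) at device-dependent rates.
Every activity is normalised by linearly interpolating cumulative time onto
a 100 m distance grid and differencing; a trailing partial interval
(< 100 m) is discarded rather than extrapolated. Units are fixed
package-wide: seconds internally, min/km for every pace a user sees, metres
for grids and kilometres for session summaries. Training weeks are rolling
7-day blocks anchored at race-day (week 0 is race week, counting backwards),
not calendar weeks — an activity d days before the race belongs to week
ceil(d/7) − 1.

Pauses inside an activity are not modelled: each activity's samples are
treated as one contiguous effort. Race-distance efforts and time trials stay
in the activity stream; the fastest-pace mining assumes maximal efforts
happen naturally during training.

## Fastest-pace mining and the four fitness models

For one activity, the fastest-pace table maps each window length w·100 m to
the minimum mean pace over all contiguous windows of that length; windows
never span activities. A runner's cumulative table is the elementwise
running minimum over their date-ordered activities.

A caveat worth stating explicitly: the per-activity table is **not**
guaranteed monotone in distance. For contiguous windows, a longer window can
be *faster* than the best shorter window (per-100 m paces 3, 7, 3 give a
best 200 m mean of 5.0 but a best 300 m mean of 4.33, because the slow
middle interval is diluted by two fast edges). The intuition "longer cannot
be faster" holds only for efforts whose pace fades monotonically — the shape
of a maximal effort — and that is the only situation in which the package's
tests assert it. The table therefore stores raw window minima, which is also
what the brute-force enumeration oracle checks.

* **FP** uses the cumulative fastest 1500 m / 5 km / 10 km paces directly.
* **FTP(t)**, t ∈ {45, 50, 55, 60} min, is the fastest mean pace over any
  contiguous within-activity span of cumulative duration **≥ t** (not
  exactly t: the 100 m grid rarely hits t exactly, and the ≥-span value is
  well defined and conservative). FTP(45) ≤ FTP(60) always holds because
  every ≥ 60-min span is also a ≥ 45-min span.
* **VO2max** applies the Daniels–Gilbert formulas to the fastest pace at
  every available distance between 1500 m and 30 km in 100 m steps, and
  summarises with the mean and the **population** SD (ddof = 0; the
  estimates form the whole population of mined distances, not a sample).
* **CV** estimates T_lim(d) = d · fastest_pace(d) over the same distance
  range and fits distance on T_lim by ordinary least squares; the slope is
  critical speed CS (m/s) and the intercept D′ (m). T_lim estimated this way
  is an overestimate whenever the mined pace was not a true exhaustive
  effort; the fit needs at least two distinct distances and raises a
  degenerate-fit error otherwise.

The weekly feature matrix covers weeks 11…0 before race-day; week w uses all
activities up to and including week w, so inactive weeks carry the previous
cumulative values forward. The combined (CB) representation concatenates the
11 model features, plus age and sex.

**Prediction harness.** Marathon-time prediction is evaluated with
runner-grouped 10-fold cross-validation (a test runner contributes no
training rows), mean absolute error in minutes per model × week. Missing
features are imputed with the training-fold mean, fitted inside the fold —
no test leakage. The default regressor is scikit-learn gradient boosting
(squared-error loss, learning rate 0.1, 100 boosting stages) but the harness
accepts any fit/predict factory; the algorithm menu is configuration, not
architecture.

## Case-based training recommendation

A training case is one runner-week: 18 features (sex, session count, weekly
volume, distance-weighted mean pace, longest run, fastest/slowest 1/5/10 km
window paces for the week and to date), the runner's marathon time, and a
pointer to the week of training that runner actually did next. Retrieval is
strict 1-NN: among same-sex, same-week cases with marathon times within
1 minute of the adjusted goal, the Euclidean nearest neighbour on z-scored
features wins, and its stored next week is returned verbatim with
provenance — plans are never synthesised. Normalisation statistics are
fitted per (week, sex) case base; missing features map to the base mean
(z = 0); an empty goal window widens to ±2, ±4, ±8 minutes and then fails
explicitly. Ties break by goal-time proximity, then case id.

The 4-week ensemble queries the four most recent weeks; in ordered mode
both the query weeks and each candidate runner's 4-week block are first
sorted ascending by longest-run distance (the training-load proxy), so that
out-of-phase training blocks align before matching; rank-i comparisons use
the normalisation statistics of the i-th anchor week. The globally most
similar retrieved case supplies the recommendation.

The goal-adjustment sweep evaluates δ ∈ [−20, +20] minutes with
runner-grouped folds. The δ = 0 reference is the runner's **actual executed
next week** (not their plan, which the data cannot distinguish); the
runner's own cases are excluded from the base, so δ = 0 returns the nearest
neighbour rather than the runner themselves.

## Training-disruption risk

An activity starts a *break* when strictly more than n days pass before the
next activity (n ∈ {7, 10, 14}); the label for activity i asks whether any
later activity dated within m days of i starts such a break ("within m
days" is calendar days, which is the only reading consistent with irregular
activity spacing; m = ∞ means up to race-day). Labels whose look-ahead
window extends beyond race-day are withheld, not guessed. History features
use the same n as the label (the least surprising coupling with the
prediction target). ACR uses rolling 7-day blocks anchored at the instance
date and is missing until the history spans the chronic window; a zero
chronic load is guarded as missing rather than divided by.

Because positives are rare, training folds are rebalanced by random
undersampling of negatives *after* the runner-grouped split; test folds
keep their natural imbalance. The default classifier menu is logistic
regression (L2, C = 1, tol = 1e-4), random forest (100 trees) and Gaussian
naive Bayes, all via factories. Beyond hard classification, the
positive-class probability is exposed as a risk score; calibration bins
scores into deciles and correlates bin mean score with bin break incidence
(Pearson and Spearman). Alert text renders the score to one decimal with
either the cohort-incidence or the relative-risk template.

## PB prediction and pacing

Race records carry nine per-km segment paces (5 km splits plus the final
2.195 km of the 42.195 km distance). Profiles are expressed relative to the
profile-implied mean race pace, so the length-weighted mean relative pace is
exactly 1. A runner's PB is their fastest race (ties broken by earliest
year); each non-PB race pairs with the PB to form one case.

Retrieval is cosine similarity over the 9 relative non-PB paces plus one
min-max-scaled non-PB finish-time coordinate (scaling over the sex stratum
keeps the extra coordinate commensurate with the unit-scale relative paces);
cases are sex-stratified and a query runner's own cases are always
excluded. Three combination strategies: *best* (fastest retrieved PB),
*mean* (similarity-weighted mean of PB finishes and profiles — weighting by
similarity preserves the unit weighted-mean identity, so plan paces always
reproduce the predicted finish), and *even* (the PB profile with minimum
coefficient of variation, the natural formalisation of "most even").
Evaluation uses runner-grouped folds (splits are therefore only
approximately 10/90), percentage finish-time error and plan cosine
similarity, averaged over k = 1…20 per case and then across cases.
In-race feedback compares current to planned segment pace with a default
tolerance of 3 s/km (configurable): faster than plan − tolerance →
slow down; slower than plan + tolerance → speed up.

## The synthetic-data generator

The generator exists so every pipeline is testable end-to-end without
proprietary data. One latent mechanism drives everything: each runner has a
critical speed CS_true (truncated normal, 3.3 ± 0.4 m/s, females 0.25 m/s
slower, bounds 2.3–4.6) and capacity D′ (uniform 120–260 m), and every
session and race pace derives from the hyperbola v(T) = CS + D′/T.

* **Programme.** 16 weeks split base/strength/speed/taper (5/4/5/2), 3–6
  sessions per week, weekly volume = base volume × a period multiplier
  (ramping 0.70 → 1.15, tapering to 0.40). Base weekly volume increases
  with CS (20 + 18·(CS − 2.5) km ± 4), so faster runners train faster *and*
  longer — the monotone structure the recommender sweep relies on. The long
  run is anchored to a fixed weekday slot so natural gaps never exceed
  7 days.
* **Maximal efforts.** Time trials at 1500 m / 5 km / 10 km / 21.1 km are
  scheduled through the programme. An all-out effort is paced on the
  runner's own curve — an initial sprint at 1.9·CS up to the kink where the
  hyperbola takes over — so **every prefix distance is covered in the
  minimum achievable time**, and the kink is written as an explicit sample
  so grid interpolation is exact. Easy/long/tempo runs are steady efforts at
  0.70/0.72/0.85·CS, capped at 21 km so no distance in the mining range is
  ever dominated by an easy-pace window. Consequently, with zero noise the
  final cumulative fastest table lies exactly on the generative hyperbola
  and the CV fit recovers CS_true and D′_true to floating-point precision —
  the identifiability property the recovery tests assert. Noise is a single
  multiplicative factor on each activity's times (default SD 2%).
* **Fitness ramp.** CS ramps linearly from (1 − ramp)·CS_true at programme
  start to CS_true nine weeks out, then plateaus; the ramp fraction is drawn
  per runner (uniform 3–20%), uncorrelated with CS_true. Early-week paces
  therefore genuinely under-identify race-day fitness — which is why weekly
  prediction error falls as race-day approaches — while the plateau keeps
  all late maximal efforts on a single hyperbola, preserving exact
  noiseless recovery.
* **Disruptions.** After each activity a break of 8–21 days begins with
  probability expit(logit(base) + coeff·(ACR − 1)); base rate 0.02 per
  activity (a free knob, not an empirical claim) and coefficient 2.0 (the
  simplest monotone link for "load spikes raise risk"). Short 4–7 day
  non-injury gaps are injected independently (rate 0.04) so the labeller
  sees realistic negatives; break lengths 8–21 bracket the n ∈ {7, 10, 14}
  thresholds. Subsequent activities shift later and anything pushed onto or
  past race-day is dropped; ground-truth break events are returned for
  evaluation.
* **Races.** Marathon speed is 0.90·CS with per-race noise (SD 3.5% male,
  2% female); segment paces follow a nine-segment slowdown template scaled
  by a per-runner split bias (mean 0.06 male / 0.03 female, with larger
  male race-to-race wobble), renormalised so the length-weighted mean
  relative pace is exactly 1. Females' tighter variances make their races —
  and hence their PBs — more predictable, matching the directional pattern
  the evaluation checks. Sex ratio defaults to 74/26 M/F.

**What the generator does not emulate:** GPS noise and pauses, terrain,
elevation and weather, heart-rate or power channels, true injury biology
(breaks are a proxy by construction), pacing collapse ("hitting the wall")
beyond the smooth slowdown template, runners who drop out before race-day,
and any correlation between training content and split behaviour. Passing
tests therefore demonstrate that the estimators recover the structure this
generator encodes — not that the same accuracy would be achieved on real
activity streams.

## Evaluation scales and numerical conventions

Test and reference computations use deliberately modest problem sizes — 30
to 150 runners for pipeline checks, 60 runners for the weekly-error trend,
120 for the goal-adjustment sweep, and roughly 1,200 runners (≈ 50,000
labelled instances) for risk-score calibration — chosen so the full suite
runs comfortably on a single CPU while leaving each directional effect
clearly resolved. Stochastic checks fix their seeds; every simulation stage
derives its generator from (master seed, stage, runner index), so any output
is a pure function of configuration and seed.

Other conventions: tie-breaks are always deterministic (distance, then goal
proximity, then lexicographic id); quantile-based deciles collapse ties by
right-searching bin edges; constant score vectors make calibration
undefined and raise rather than returning NaN; and CSV writers emit a fixed
column order so identical runs produce byte-identical files.

## Known limitations

The CV-model T_lim values are systematic overestimates on real data (mined
paces are rarely exhaustive efforts), so absolute CS/D′ values should be
read as rankings rather than physiology. FTP span search is quadratic in
activity length, acceptable at 100 m granularity but not for per-second
streams. The recommender reuses a single case verbatim, inheriting whatever
idiosyncrasies that runner's week contained; combining k > 1 plans is out
of scope. Risk classification inherits the class-imbalance limits discussed
above — precision on rare long breaks is intrinsically low, which is
precisely why the calibrated risk score, not the hard label, is the
user-facing output.
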