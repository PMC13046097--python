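# Methods

`hypnoval` evaluates a contactless (under-mattress) sleep-stage tracker
against reviewer-annotated polysomnography. This note documents the
evaluation procedure, the synthetic cohort that stands in for private
study data, the numerical choices, and what the tests do and do not
establish about real recordings.

## Harmonization and the comparison grid

Reference scoring follows the AASM convention: two certified reviewers
stage each 30-second epoch as WAKE, N1, N2, N3 or REM, and a third
reviewer adjudicates epochs where they disagree. The device emits one of
WAKE, LIGHT, DEEP, REM (plus a bed-ABSENT mark) per 6-minute window and
does not separate N1 from N2. Comparison therefore happens in a common
four-stage vocabulary (order WAKE, REM, LIGHT, DEEP — canonical for all
confusion matrices):

1. map the consensus PSG5 annotation: N1, N2 → LIGHT; N3 → DEEP
   (mapping happens *before* smoothing so N1 and N2 votes pool into
   LIGHT inside each window);
2. majority-smooth onto 6-minute windows — the stage with the highest
   count of 30-s epochs wins; ties break by the fixed priority
   WAKE > REM > DEEP > LIGHT (conservative: a tie never invents sleep,
   and within sleep never invents depth); a trailing partial window is
   scored by majority of its available epochs rather than discarded;
3. broadcast both the smoothed consensus and the device output back to
   30-s epochs, so counts are comparable across studies that report
   30-s epoch totals while respecting the device's 6-minute decision
   granularity.

Intervals are half-open `[start, end)`, times are seconds from a
per-night origin, epoch indices are 0-based. Device ABSENT windows are
excluded from all counts by default; recoding them as WAKE is available
(`absent_policy="as_wake"`) because published pipelines do not always
state their handling.

## Clock synchronization

The recorder and the device keep independent clocks. Both observe the
same respiratory motion, so the offset is estimated by maximizing the
Pearson correlation between the two breathing traces over an exhaustive
lag grid (default ±300 s in 0.5 s steps — wide enough for realistic
drift, cheap to search). Both series are linearly resampled to the
higher rate; correlation uses only the overlapping support at each lag
(no zero-padding, which would bias edge lags). A peak correlation below
0.3 (roughly 6 null SDs for the series lengths involved) triggers a
warning and a fallback to zero offset. The corrected device hypnogram is
re-snapped to the nearest 30-s boundary of the reference grid; exact
half-grid ties round toward zero shift. A shift-sensitivity table
(±90 s in 30-s steps) reports how much every per-stage sensitivity and
specificity moves under deliberate misalignment.

## Agreement statistics

Per night, the valid 30-s epochs fill a 4×4 confusion matrix (rows
reference, columns device) from which we derive: one-vs-rest
sensitivity and specificity per stage, overall accuracy, Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products (NaN flag
when p_e = 1), and the sleep–wake collapse (SLEEP = REM ∪ LIGHT ∪
DEEP), for which se_wake ≡ sp_sleep and sp_wake ≡ se_sleep hold by
construction. Cohort summaries average per-night values; nights where a
stage has zero reference support are excluded from that stage's average
rather than imputed, so prevalence-free metrics are not biased by
absent stages. The 95% CI is the normal approximation
mean ± 1.96·SD/√n (a seeded percentile bootstrap is available).
Pooled-epoch matrices are emitted separately and labeled as such.

Epochs are also stratified by whether the two reviewers agreed before
adjudication; performance is reported per stratum and compared with a
pooled two-proportion z test. κ is not a proportion, so its z score is
computed on the pooled observed-agreement proportion — the closest
proportion-valued surrogate — and labeled accordingly. Epochs
contributed by a trailing partial smoothing window fall outside the
reviewers' span and belong to neither stratum.

## Night-scale measures

For a harmonized hypnogram over the analysis window: TI(stage) = epoch
count × epoch duration; TST = window − TI(WAKE); NE(stage) = number of
maximal same-stage runs; stage changes = adjacent differing epoch
pairs at native resolution. PI(stage) uses the full analysis window as
denominator by default — the convention the published sleep-quantity
tables are arithmetically consistent with — so the four PI values sum
to 100%; a TST denominator is available as an option. Paired
device-reference statistics: MAE, Bland–Altman bias with 95% limits of
agreement (bias ± 1.96·SD of differences), proportional bias as the
least-squares slope of differences on pairwise means, and a seeded
RANSAC regression of device on reference values (residual threshold
defaulting to the median absolute deviation of an initial
least-squares fit; 1000 trials; R² and the slope's t-test computed on
the inlier set). Because TST + TI(WAKE) is the window length,
MAE(TST) = MAE(TIWake) and bias(TST) = −bias(TIWake) exactly — these
identities are asserted in the tests. Sleep-onset latency and WASO are
out of scope: without in-bed boundary sensors they cannot be assessed
in free-living recordings.

## Subgroup tests and the survey

Per-participant absolute errors of TST, the TI and PI measures and the
episode counts are compared across metadata subgroups (sex, age group,
BMI group, bed partner, mattress type and thickness, subjective sleep
duration, self-reported quality, night awakenings) with Kruskal–Wallis
(medians; χ² approximation) and Brown–Forsythe (variances; ANOVA on
|x − group median|). Holm–Bonferroni step-down correction is applied
with one family per test type spanning all grouping × measure
combinations by default (`per_grouping` is available) — the family
structure is a genuine design choice because published protocols
rarely state it. Age bins default to {<30, 30–44, 45–59, ≥60} and BMI
to the WHO cuts {<18.5, 18.5–25, 25–30, ≥30}; both are configurable.
The paired ordinal sleep-quality survey (five levels, very poor …
very good) is tabulated per condition with an improved / identical /
deteriorated transition partition.

## The synthetic cohort

No public data accompany the protocol, so a seeded generator emulates
the study conditions; its defaults are fixed once from the cohort-level
figures the protocol reports and are not tuned per experiment.

* **Architecture.** Ground truth is a first-order Markov chain over
  the five stages on 30-s epochs: T = (1−a)·I + a·1πᵀ with switching
  rate a = 0.06 per step (mean dwell ≈ 8–13 min) and stationary
  π = (0.25, 0.07, 0.23, 0.27, 0.18) for (WAKE, N1, N2, N3, REM).
  Nights span 1100–1300 epochs (~9.2–10.8 h) with 20–60 epochs of
  quiet wake padded on either side, so the realized wake share of the
  window is ≈30% and mean TST ≈ 7–7¼ h, matching the cohort the
  pipeline was designed for. The rank-one form makes the stationary
  distribution exact, which the tests check against an
  eigen-decomposition oracle; the price is that stage-to-stage
  transition structure (e.g. the N2→N3→REM cycle) is not physiological.
* **Reviewers.** Each reviewer draws epoch-wise from a 5×5 confusion
  matrix (diagonals 0.70–0.88) whose off-diagonal mass concentrates
  where human scorers actually disagree: N2 ↔ N3 and N1 ↔ wake/REM.
  This yields an inter-rater κ near 0.67 (5-stage) and 0.76
  (sleep–wake). The adjudicator defaults to the truth (so consensus
  errors come only from joint reviewer mistakes); an own-confusion
  adjudicator is configurable.
* **Device.** The truth is harmonized and majority-smoothed to 6-min
  windows, then passed through a 4×4 emission matrix — error is
  conditioned on the smoothed truth because that is the granularity at
  which the real device decides. The default emission sends most
  misclassification into LIGHT (e.g. 40% of deep and 37% of REM
  windows), reproducing the published confusion structure of this
  device class. ABSENT head/tail windows (0–3 each) and a configurable
  clock offset complete the output. Per-group error multipliers scale
  the off-diagonal mass (diagonal floored at 0.02) for subgroup power
  studies.
* **Breathing.** Both devices observe one latent sinusoid whose rate
  follows a clipped per-minute random walk (12–18 breaths/min,
  SD 0.5/min — enough drift to break the periodicity that would
  otherwise alias the lag search). Each trace has its own sampling
  rate (4 / 3.5 Hz) and an independent noise stream; the default noise
  SD of 0.1414 puts the amplitude-RMS SNR at ≈5.
* **Metadata.** Demographics, PSQI components, mattress and
  environment columns are drawn from the cohort's published
  distributions (age 39.9 ± 11.4, BMI 23.9 ± 3.3, 59% women, 55% bed
  partner, 41.4% sensor disturbance, …). The subjective
  short-sleep-duration group is derived from the sleep-duration
  questionnaire component.

All randomness flows through `numpy.random.SeedSequence`; subject *i*
uses spawn key (i+1, stage), so cohorts are byte-reproducible from the
manifest and stable under changes of cohort size.

What passing tests show — and do not. The generator validates the
*pipeline arithmetic* (a faultless device scores perfectly; injected
emission matrices, offsets and group effects are recovered; the
statistics are calibrated). It does not establish device performance on
real data: real hypnograms have non-Markovian bout-length
distributions, reviewer errors correlate in time rather than epoch-wise,
device errors depend on movement and cardiorespiratory signal quality
rather than being conditionally independent given the stage, and real
breathing traces contain apneas and posture artifacts.

## Problem sizes and numerical choices

Experiments are sized to run on one CPU core in minutes: the reference
cohort uses 117 nights (the study's size); offset recovery uses 100
nights of 2–2.5 h with a ±120 s lag search (offsets under test are
≤90 s); emission recovery uses 50 nights with a 200-night companion run
that pins every cell's Monte-Carlo SE below ~0.9 percentage points;
statistical calibration uses 10,000 null replicates of three normal
groups of 100 (Brown–Forsythe is conservative below ~50 per group, so
calibration is asserted in the moderate-sample regime); subgroup power
uses 20 replicate cohorts. Ties in the majority vote and in offset
snapping are resolved deterministically as described above; degenerate
inputs (flat signals, empty strata, all-identical values, zero-variance
groups) return flagged values or raise typed errors rather than
propagating NaNs silently.

## Known limitations

* The Markov architecture has exponential bout lengths; survival-based
  bout statistics of real sleep are heavier-tailed.
* The z score attached to κ in the strata comparison tests the
  observed-agreement proportion, not κ itself.
* The stage-change count is defined at native resolution as adjacent
  differing pairs; published tables of this quantity are not always
  internally consistent, and no attempt is made to reproduce them.
* Holm family structure and subgroup bin edges follow the defaults
  documented above; studies that define different families or bins will
  not be exactly reproduced without configuration.
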