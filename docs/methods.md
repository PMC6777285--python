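# Methods

## Scope and model of the data

`hrconcord` analyses paired heart-rate (HR) streams from a criterion device
(chest-strap monitor, treated as the reference) and one or more wrist-worn
trackers, collected under two conditions: a graded laboratory cycling session
and a free-living wear day. All devices are assumed NTP-synchronized, so
streams are aligned purely by timestamp; no cross-correlation lag search is
performed. The unit of analysis is the 10-second epoch on a Unix-aligned grid
(timestamp seconds ≡ 0 mod 10).

## Epoching and matching

**Extraction rule.** A 1 Hz stream contributes to an epoch the instantaneous
reading whose timestamp equals the epoch start; a 0.1 Hz stream is already
grid-aligned. The instantaneous rule is the default because it is the only
rule all sampling rates can satisfy uniformly; a window-mean alternative
(`rule="mean"`, averaging readings in [start, start+10 s)) is available for
sensitivity checks. Epochs without a reading are absent, never zero-filled.

**Zero filtering.** Wrist sensors emit literal 0 bpm on dropout. Matching
drops every pair in which either device reads 0: tracker zeros are dropout
artefacts, and a 0 bpm criterion is nonphysiological and would break MAPE's
division by the criterion. Matching is an inner join on epoch starts,
pairwise tracker-vs-criterion by default; a complete-triplets mode restricts
to epochs available from all devices simultaneously (secondary analysis).

**Inclusion.** A participant–phase–tracker set enters the pooled analysis
with ≥ 60 matched epochs (10 min) in the laboratory and ≥ 1,080 (180 min)
free-living; both boundaries inclusive. Excluded sets carry machine-readable
reasons in the exclusion log. Wear time is (nonzero epochs) × 10 s.

## Agreement statistics

**ICC.** ICC(2,1) — two-way random effects, single measure, absolute
agreement — with rows = matched epochs and columns = {criterion, tracker}
(k = 2), from the ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

with Shrout–Fleiss F-based 95% CIs. Epochs are pooled across participants;
this ignores within-participant correlation and therefore understates
uncertainty (the CIs are tight because n is thousands of epochs, not tens of
participants). Pooling is deliberate: it reproduces how pooled validation
analyses with per-epoch rows behave, and a per-participant error summary is
emitted alongside. A participant-random-effects ICC is a noted alternative,
not implemented. Degenerate input with no variance anywhere returns ICC 0
with a warning. Qualitative bands: weak < 0.50 ≤ moderate < 0.75 ≤ strong
< 0.90 ≤ very strong; boundaries belong to the upper band.

**Errors.** MAE = mean |tracker − criterion| (bpm); MAPE =
mean(|tracker − criterion| / criterion) × 100, with 10% as the validity
cutoff; mean bias = mean(tracker − criterion), so underestimation is
negative. 95% CIs use the normal approximation mean ± 1.96·SD/√n on epoch
level means — symmetric and, like the pooled ICC, optimistic about n.

**Bland–Altman.** Limits of agreement = mean difference ± 1.96 × sample SD
(ddof = 1) of the per-epoch differences; with zero spread the limits collapse
onto the mean. The per-pair (mean, difference) table is emitted for plotting.

**Outlier screen.** Participants whose laboratory tracker-vs-criterion
Pearson r is below 0.3 are flagged (constant-valued devices flag too, since r
is undefined); participants with < 3 laboratory pairs are "not evaluable".
Flagged participants can be removed for a sensitivity reanalysis
(`exclude_outliers=True`).

**Reporting precision.** ICC to 2 decimals, MAE/MAPE/bias to 1, rounding
half-up; full precision is retained on the result objects.

## Deciles

Criterion values over the matched epochs are ranked and split into ten
equal-count bins (sizes ⌊n/10⌋ or ⌈n/10⌉), ties broken by epoch timestamp,
then participant id — a rank split, not value-based quantile cuts, so decile
sizes are balanced even with heavily tied integer bpm data. Summaries are
five-number statistics plus mean per device and the mean per-decile
difference. Deciles are computed per phase, pooled across participants, on
each tracker's own matched set; a per-participant mode is available through
the same functions.

## MVPA zones

The moderate-to-vigorous threshold is 64% of the age-predicted maximum
HR (220 − age), applied per participant; an epoch is MVPA when
HR ≥ 0.64·HRmax (boundary inclusive; comparisons use a 1e-9 tolerance
because 0.64·(220−age) is not exactly representable in binary floating
point). The 2×2 table pools epoch counts over participants per phase ×
tracker: tp = MVPA under both devices, fn = criterion-MVPA missed,
fp = tracker-MVPA unconfirmed, tn = both below. Sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), accuracy = (tp+tn)/total, as percentages rounded
half-up to 2 decimals. Raising the cutoff monotonically shrinks tp and
tp+fp; fp alone is not monotone (an epoch can migrate from tp to fp when the
criterion falls below the raised threshold while the tracker stays above).
Bout-level MVPA detection and additional zone cuts (e.g. vigorous) are out
of scope; epochs, not bouts, are counted.

## Synthetic cohorts

**What it emulates.** The generator produces, per participant, a 1 Hz
ground-truth trajectory and three device streams (criterion at 1 Hz, one
tracker at 1 Hz, one at 0.1 Hz) for both phases, plus a roster
(id, age ∈ [21, 50], resting HR ∈ [55, 75] bpm by default — the age range of
the emulated study population).

**Truth trajectory.** A deterministic protocol backbone with first-order
exponential transitions (time constant 30 s, a physiological on-kinetics
scale for cycle ergometry) plus a mean-reverting Ornstein–Uhlenbeck wander
(stationary SD 2 bpm, correlation time 60 s) so that rank and decile
structure is nontrivial. Laboratory: 5 min seated rest at resting HR, four
5-min stages targeting 45/55/65/75% of HRmax, 5 min recovery; empirical
stage means stay within the ±10 bpm protocol tolerance. Free-living: 12 h at
a 45%-of-HRmax baseline with one 10-min bout at 72% of HRmax placed
uniformly at random within the day (one bout per equal slice when several
are requested). Outside bouts the trajectory is clipped 1 bpm below the MVPA
threshold and inside bouts 1 bpm above it, so the zone truth of every second
is unambiguous by construction — a deliberate idealisation that makes
zone-detection errors attributable to the sensor model alone. Values are
rounded to integer bpm and clipped to [30, HRmax].

**Device error model.** reading = truth + b₀ + b₁·(truth − resting HR) +
N(0, σ₀ + σ₁·(truth − resting HR)), floored at 0 bpm; with probability p the
reading is replaced by a literal 0 (dropout). b₁ captures the
motion/perfusion-driven degradation of optical HR at higher intensities; the
heteroscedastic σ term reproduces the growing scatter at high HR. Defaults
for the study-condition scenario: criterion p = 0.02 and no error (the chest
strap is near-truth); 1 Hz tracker b₀ = −5.7 bpm, σ₀ = 3, σ₁ = 0.02,
p = 0.03 (a well-behaved consumer tracker); 0.1 Hz tracker b₀ = −2,
b₁ = −0.08, σ₀ = 3, σ₁ = 0.05, p = 0.05 (a low-cost tracker whose
underestimation grows with HR). Bias magnitudes follow the laboratory mean
biases reported for the emulated devices (−5.7 and ≈−9.7 bpm at cycling
intensity); noise and dropout levels are chosen to land MAPE in the
realistic 5–10% band. In-memory streams carry float bpm (so a −9.7 bpm bias
is exact); CSV export rounds to non-negative integers as real exports do.

**What it does not emulate.** No PPG optics or motion-artifact physics, no
accelerometry, no device-specific smoothing/latency, no diurnal HR rhythm,
no systematic nonwear differences between devices (nonwear is shared truth
plus independent dropout). Passing tests therefore demonstrate the
*pipeline's* correctness and statistical behaviour under known error
structure, not any real device's accuracy.

**Determinism.** All randomness flows from integer seeds; per-stream
sub-seeds are derived by hashing (participant, phase, device) with the
cohort seed, so regenerated cohorts are byte-identical and adding a
participant does not perturb the others' streams.

## Numerical choices and degenerate inputs

* Half-up decimal rounding (via `decimal.Decimal`) wherever report
  percentages are produced, matching the convention of published tables.
* Epoch grid anchored at Unix-aligned 10-s boundaries; shifting all
  timestamps by whole hours leaves every pair count unchanged.
* ICC with zero residual variance (perfect agreement) returns a collapsed
  CI rather than attempting the F interval; all-constant input returns 0
  with a warning.
* Decile ties resolved by (criterion value, epoch timestamp, participant id)
  lexicographic stable sort.
* `match_pairs` on disjoint grids returns an empty result, not an error;
  participant or phase mismatches are errors.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts of 2–10
participants (a laboratory session is 1,800 s; a wear day 43,200 s at 1 Hz),
100-replicate Monte-Carlo checks on single-session data, and 10,000-epoch
bias-recovery checks; these sizes give stable statistics (SEM of the
recovered bias ≈ 0.05 bpm at n = 10,000) while keeping a full run in
seconds.

## Known limitations

* Pooled-epoch ICC and normal-approximation CIs ignore the within-participant
  correlation structure; they describe the pooled epoch population, not
  participant-level generalisation.
* The MAPE denominator is the criterion value, so the statistic is asymmetric
  and inflated at low HR.
* The generator's zone-clipped free-living trajectory cannot produce
  criterion values exactly at the MVPA threshold, so boundary behaviour is
  exercised by dedicated unit tests rather than by simulation.
* Only two devices enter each agreement computation (k = 2); multi-tracker
  comparisons are separate pairwise analyses plus the complete-triplet
  restriction, not a joint model.
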