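# Methods

This note documents the models and procedures implemented in
`nicugaze`, the assumptions behind the synthetic cohort generator, and
the numerical choices made where the design was genuinely open.

## The exposure composite

For one parent of one infant,

```
exposure_words = word_frequency × presence_hours_14d
word_frequency = Σ (channel words apportioned to presence) / presence hours during the recording
```

* **Channels.** The recorder classifies adult words into female and male
  counts per timestamped segment; female words are attributed to the
  mother and male words to the father.  Overlapping-speaker ambiguity
  (e.g. staff speech while a parent is present) is not modeled on the
  analysis side; the generator includes a modest background word rate so
  that the pipeline is exercised under that contamination.
* **Daily window.** Only 07:00–22:00 of each day is used, for both the
  word-frequency numerator/denominator and the 14-day presence sum.
  Intervals are half-open `[start, end)` at minute resolution, so
  abutting intervals never double-count a boundary minute; intervals
  spanning midnight are split before clipping.
* **Apportionment.** A segment partially overlapping a presence interval
  contributes its words in proportion to the overlapped fraction of the
  segment's full duration — unbiased if words arrive uniformly within a
  segment.  Equivalence with a per-minute counting oracle is enforced in
  the tests to 1e-9 relative.
* **Imputation.** When a parent has zero presence during the recording
  day the word frequency cannot be observed.  Precedence: (a) absent
  father in a single-parent family → 0; (b) the co-twin's observed value
  for the same role; (c) the site median of observed frequencies for
  that role.  Site medians use observed values only.  The source of each
  frequency is reported in `exposure.csv`.
* **Diary coverage.** How to treat infants with incomplete diaries is
  not prescribed; the module computes presence from whatever intervals
  exist and leaves any coverage thresholding to the user.

## Gaze coding and condition scores

Paradigm geometry and timing: central stimulus 9.6°×10.2°, lateral
distractor ~12° left or right, SOA 1000 ms, distractor duration
2000 ms, analysis window 150–1000 ms after lateral onset, 30 Hz
video-based coding (one-frame ≈ 33 ms latency resolution).

* The central-fixation proportion is computed over the pre-lateral
  period (central onset to lateral onset); the ≥75% criterion uses that
  period as its denominator, which the source protocol leaves implicit.
* The first sample outside the central area-of-interest after lateral
  onset defines the shift latency and direction.  Disengagement is
  registered only for shifts toward the distractor starting strictly
  after 150 ms and at or before 1000 ms; a shift at ≤150 ms is
  premature (criterion iii) and one away from the cued side fails
  criterion iv.  Streams with gaps larger than one sample period
  (tolerance 1.5× to absorb timing jitter) inside the analysis window
  are flagged as unanalyzable video (criterion ii).
* Condition scores: per identity×class condition (parent/unfamiliar ×
  face/non-face), P(no disengagement) is the exact count ratio over
  valid trials, with facial expressions pooled.  Inclusion requires >2
  valid trials in *each* of the four conditions (default); because the
  rule could equally be read on the two pooled classes, a
  `pooling="pooled2"` switch applies it to pooled face/non-face counts
  instead.
* Dwell time: mean of `min(latency, 1000)` over valid trials with
  1000 ms assigned to no-disengagement trials — i.e. right-censored at
  the window end and included at the cap.  No published censoring rule
  exists for this variant; the cap rule is an explicit choice and the
  measure is secondary throughout.

## Statistics

* **Wilcoxon signed-rank** with zero differences dropped and average
  ranks for ties; effect size |z|/√N with N the retained pairs and z the
  normal-approximation statistic (no continuity correction).  The
  p-value uses the exact sign-flip distribution when there are no zeros
  or ties and N ≤ 25, else the normal approximation; the tests verify
  exact agreement with full 2^n enumeration at small N.
* **Partial Spearman** by rank-then-residualize: every variable is
  rank-transformed (average ranks), x and y are residualized on the
  ranked covariates by least squares with intercept, and the residuals
  are Pearson-correlated.  With no covariates this is exactly the
  textbook Spearman coefficient.  This is a deliberate design choice:
  it is deterministic and closed-form, and differs from
  probability-scale-residual estimators used by some software; the two
  coincide in their null behavior and closely in magnitude for
  continuous data.  p-values use the t approximation with
  df = n − 2 − #covariates; its calibration at the study's n is checked
  empirically (type-I error within [0.03, 0.07] at α = 0.05).
  Confidence intervals are seeded bootstrap percentile intervals (2000
  resamples, re-ranked per resample); the interval construction for
  rank partial correlations has no canonical closed form, so bootstrap
  is used without claiming provenance.
* **Order of operations** for the cohort analyses: per-site z-scoring of
  exposure and both gaze scores first (the two sites differ strongly in
  word counts), then the partial rank correlation.  Ordinal covariates
  (education levels) enter as level codes, binaries as 0/1; ranking
  makes the coding scale-free.  Rows with missing covariates are
  dropped listwise and the analyzed n is reported.
* **Twin-subset sensitivity**: cohorts with k complete twin pairs are
  re-analyzed on all 2^k subsets formed by all singletons plus one
  member per pair (guarded at k ≤ 20), reporting the min/median/max of
  the association across subsets.  This replaces mixed-effects
  modeling of twin clustering by design.
* No multiple-testing correction is applied; results are reported as a
  family of related estimates.

## The synthetic cohort generator

The generator's defaults are the study conditions used throughout the
tests; they were chosen once, before any calibration against test
outcomes, to echo the magnitudes a two-site family-centered NICU cohort
would show:

* 25 + 38 infants in sites A and B, 7 complete twin pairs, one 16-hour
  recording day (start 06:00–07:00) within a 14-day diary.
* Word frequencies are log-normal per site and role: mothers centered
  near 1100 words/h in the single-family-room-like site A and 230 in
  the open-bay-like site B; fathers near 330 and 15.  Presence-hour
  medians differ likewise (A: 8.0/4.2 h per day for mother/father; B:
  11.0/0.9).  These anchor the synthetic scale to plausible values
  without claiming to reproduce any cohort's data.
* Twins share a family: the same parents (hence the same latent
  frequencies and presence means) plus a family-level log-scale random
  effect (SD 0.3).
* Parents are absent on the recording day with probability 0.02
  (mothers) and 0.2 (fathers); ~5% of families are single-mother — the
  three imputation paths all occur at realistic rates.
* **Latent coupling.** Each infant's trait t is built from the
  within-site normal scores z of log total true exposure:
  t = ρ·z + √(1−ρ²)·ε (a bivariate-normal copula on realized
  exposures), giving exact control of the within-site rank correlation
  target, ρ = 0.35 by default.  The trait raises the log-odds of *not*
  disengaging from faces by `trait_effect` (default 1.0) per SD;
  non-face trials keep their base rate.  Base no-disengagement rates
  are 0.55 (face) and 0.24 (non-face).
* Trials are corrupted at rate 0.2 by one of the four real failure
  modes, chosen uniformly, leaving a median of 8–10 valid trials per
  pooled condition out of 12 per identity×class cell.
* Disengagement latencies are drawn from a log-normal (median 400 ms,
  σ = 0.35) truncated to the 150–1000 ms window by inverse-CDF
  sampling.  The true latency distribution of infant disengagements is
  not established; this truncated log-normal is an explicit assumption.
* Gaze-stream mode renders each trial outcome as 30 Hz samples with
  Gaussian positional noise (default 0.5°); coded-trial mode emits
  `TrialRecord` rows directly and is the fast default.

**What the generator does not emulate:** real word-count measurement
error beyond Poisson noise, diary misreporting, infant state (sleep,
feeding) effects on trials, covariate–outcome associations (covariates
are generated independently of the trait, so adjusted analyses are
exercised under the null for the covariates), site differences in
gaze behavior, and drop-out between the neonatal period and the
7-month visit.  Passing tests therefore demonstrate that the pipeline
recovers what it is pointed at under a faithful generative model — not
that any real cohort satisfies that model.

## Parameter recovery and calibration

Two replicate studies (run in the test suite) characterize the
estimator at the study's sample size:

* With injected ρ = 0.35 and n = 63, the median adjusted partial r_s
  over 200 simulated cohorts must lie within ±0.08 of a large-sample
  oracle value obtained by simulating the latent measurement model
  directly at n = 100 000 (binomially sampled condition scores over the
  valid trials attenuate the correlation below ρ; the oracle carries
  that attenuation, about 0.30 for the defaults).
* With ρ = 0, the covariate-adjusted analysis must reject at α = 0.05
  in 3–7% of 1000 replicates.

Replicates run the full pipeline (simulate → exposure → scoring →
association) with bootstrap intervals disabled; problem sizes (200 and
1000 replicates of a 63-infant cohort, one 100 000-row oracle) keep the
whole suite around five minutes while leaving the Monte-Carlo error of
the checked quantities well below their tolerances.

## Determinism

Identical config + seed reproduces every table bit-for-bit: all
randomness flows from `numpy.random.default_rng(seed)`, bootstrap
intervals are seeded, timestamps are built from integer minutes, and
`results.json` is serialized with sorted keys.
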