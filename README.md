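# nicugaze

Parental speech exposure in the NICU and preterm infants' face preference.

Very preterm infants (born before 32 gestational weeks) are at risk for
atypical social-cognitive development, and the amount of parental talk
they hear during neonatal intensive care is a candidate early marker.
`nicugaze` is a tested, reusable pipeline for the analysis that links the
two measurements:

* **Exposure to the parents' speech.** A wearable recorder's adult word
  counts (female/male words per segment) are fused with a 14-day
  caregiver-presence diary.  For each parent,

  ```
  exposure = (words while present during the recording day / hours present)
             x presence hours over 14 days
  ```

  restricted to the 07:00–22:00 active-care window, with imputation for
  parents absent on the recording day (co-twin's value, else the site
  median; an absent father in a single-parent family contributes zero).

* **Face preference.** In an eye-tracking overlap paradigm at 7 months
  corrected age, a central face or matched non-face pattern is followed
  (1000 ms SOA) by a lateral distractor.  Trials are coded for gaze
  disengagement in a 150–1000 ms window, filtered by four validity
  criteria (≥75% central fixation, analyzable video, no premature shift,
  shift toward the distractor), and averaged into per-condition
  probabilities of *no* disengagement, P(no dis).  Face preference =
  higher P(no dis) for faces than non-faces.

* **Statistics.** Paired Wilcoxon tests with the z/√N effect size;
  per-site z-scoring; partial Spearman rank correlations r_s between
  exposure and the face score adjusted for the non-face score (and
  optionally gestational age, parental education, delivery type, sex and
  birth weight); a parent-face variant adjusted for the unfamiliar-face
  score; and an exhaustive twin-subset sensitivity analysis over all 2^k
  ways of keeping one infant per twin pair.

Because cohort data of this kind are confidential, the package ships a
first-class **synthetic cohort generator** with known ground truth: two
sites with very different word-frequency and presence distributions,
twin clustering, per-role absence on the recording day, trial-level
invalidity, and a latent trait inducing a configurable rank correlation
ρ between log exposure and face preference — so every downstream stage
is testable and parameter recovery can be demonstrated.

## Worked example

```python
import nicugaze as ng
from nicugaze import gaze
from nicugaze.pipeline import build_analysis_frame

cohort = ng.simulate_cohort(ng.SimulationConfig(seed=1))   # rho = 0.35
etbl   = ng.exposure_table(cohort.infants, cohort.diary, cohort.segments)
judged = cohort.trials.join(gaze.trial_validity(cohort.trials))
scores = gaze.condition_scores(judged)
frame  = build_analysis_frame(cohort.infants, etbl, scores[scores["included"]])

wil = ng.wilcoxon_paired(frame["p_no_disengage_face"],
                         frame["p_no_disengage_nonface"])
res = ng.adjusted_association(frame, exposure_col="exposure_total",
                              ci_reps=2000, seed=1)
```

printing (see `examples/04_statistics.py`):

```
faces vs non-faces: z=-6.73, p=1.7e-11, effect size z/sqrt(N)=0.85 (N=63)
exposure vs face preference (partial r_s | non-face score): r_s=0.26 [0.01, 0.48], p=0.041, n=63
twin-subset sensitivity: 128 subsets, r_s 0.20-0.28, median 0.24
```

The first line says the 63 simulated infants disengage far less from
faces than from matched non-face patterns (a large face preference); the
second that their speech exposure correlates positively with that
preference on the rank scale after removing the non-face baseline (one
63-infant draw scatters around the model's large-sample value); the
third that the estimate barely moves across all 128 ways of keeping one
infant per twin pair.

`examples/` contains one short script per capability (simulation,
exposure, gaze scoring, statistics, full pipeline).  A thin CLI wraps
the same stages:

```bash
nicugaze simulate --seed 1 --out-dir data/
nicugaze run --seed 7 --out-dir out/        # simulation -> report.md
```

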