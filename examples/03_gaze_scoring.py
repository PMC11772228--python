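"""Code gaze streams and build per-infant no-disengagement scores.

Each trial shows a central face or non-face pattern, then a lateral
distractor after a 1000 ms onset asynchrony.  A trial is valid when the
infant fixated the centre >=75% of the pre-lateral period, the video is
analyzable, and any gaze shift starts >150 ms after distractor onset and
is directed toward it.  The per-condition score is the fraction of valid
trials without disengagement in the 150-1000 ms window.
"""

import numpy as np

import nicugaze as ng
from nicugaze import gaze

# a single trial, coded from a raw 30 Hz stream
sch = ng.generate_trial_schedule(seed=1)
trial = sch.trials.iloc[0]
stream = ng.simulate_gaze_stream(trial, disengage=True, latency_ms=400.0,
                                 noise_sd=0.0)
rec = gaze.code_trial(stream, trial)
print(f"one coded trial: shift at {rec['shift_latency_ms']:.0f} ms "
      f"({rec['shift_direction']}), central fixation "
      f"{rec['central_fixation_prop']:.2f}")
print("-> the coder recovers the injected 400 ms shift to within one "
      "33 ms video frame\n")

# a whole cohort of pre-coded trials
cohort = ng.simulate_cohort(ng.SimulationConfig(seed=1))
judged = cohort.trials.join(gaze.trial_validity(cohort.trials))
print("invalidity reasons:",
      judged.loc[~judged["valid"], "invalid_reason"].value_counts().to_dict())

scores = gaze.condition_scores(judged)
print(f"\nincluded infants (>2 valid trials in all 4 conditions): "
      f"{int(scores['included'].sum())}/{len(scores)}")
print("mean P(no disengagement): "
      f"faces {scores['p_no_disengage_face'].mean():.2f} vs "
      f"non-faces {scores['p_no_disengage_nonface'].mean():.2f}")
print("-> infants hold their gaze on faces far longer than on matched "
      "non-face patterns: a face preference.")
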