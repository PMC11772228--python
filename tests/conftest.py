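import numpy as np
import pandas as pd
import pytest

import nicugaze as ng
from nicugaze import gaze


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study conditions (63 infants, 7 twin pairs)."""
    return ng.simulate_cohort(ng.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-infant cohort for oracle-equivalence checks."""
    cfg = ng.SimulationConfig(
        n_infants_per_site=(5, 5), n_twin_pairs=2, seed=5
    )
    return ng.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    trials = default_cohort.trials
    judged = trials.join(gaze.trial_validity(trials))
    return gaze.condition_scores(judged)


def run_lean_pipeline(seed, rho, covariates=()):
    """simulate -> exposure -> scores -> adjusted association, no bootstrap."""
    from nicugaze.pipeline import build_analysis_frame
    from nicugaze import stats

    cfg = ng.SimulationConfig(seed=seed, rho_exposure_preference=rho)
    cohort = ng.simulate_cohort(cfg)
    etbl = ng.exposure_table(cohort.infants, cohort.diary, cohort.segments)
    judged = cohort.trials.join(gaze.trial_validity(cohort.trials))
    scores = gaze.condition_scores(judged)
    frame = build_analysis_frame(
        cohort.infants, etbl, scores[scores["included"]]
    )
    res = stats.adjusted_association(
        frame, exposure_col="exposure_total", covariate_cols=covariates, ci_reps=0
    )
    return res


def random_minute_intervals(rng, n, infant_id="inf000", role="mother",
                            start="2024-03-04", days=14):
    """Random minute-aligned [start, end) intervals, may span midnight."""
    base = pd.Timestamp(start)
    day = rng.integers(0, days, n)
    start_min = rng.integers(0, 24 * 60 - 1, n)
    dur_min = rng.integers(1, 10 * 60, n)
    rows = []
    for d, s, du in zip(day, start_min, dur_min):
        t0 = base + pd.Timedelta(days=int(d), minutes=int(s))
        rows.append((infant_id, role, t0, t0 + pd.Timedelta(minutes=int(du))))
    return pd.DataFrame(rows, columns=["infant_id", "parent_role", "start", "end"])
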