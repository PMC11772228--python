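"""Gaze-disengagement coding and per-infant condition scores.

A trial is coded from its gaze-sample stream: the fraction of the
pre-lateral period spent on the central stimulus, and the first
departure from the central area-of-interest after the lateral distractor
onset (latency and direction).  Disengagement counts only when the shift
toward the distractor starts inside the 150-1000 ms analysis window.

Trial inclusion criteria (video-based coding):

  i.   central fixation for >= 75% of the pre-lateral period,
  ii.  analyzable video (no gaps larger than one sample period inside
       the analysis window),
  iii. any gaze shift not premature (starts > 150 ms after lateral onset),
  iv.  any gaze shift directed toward the lateral stimulus.

Valid 0/1 no-disengagement outcomes are averaged per stimulus condition
(parent face, unfamiliar face, parent non-face, unfamiliar non-face),
pooling the facial expressions; an infant is included when every
condition has more than two valid trials (the pooled face/non-face
variant of the rule is available as an option).  Dwell time is the
latency right-censored at the 1000 ms window end, with censored
(no-disengagement) trials entered at the cap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schedule import (
    ANALYSIS_WINDOW_MS,
    CENTRAL_HEIGHT_DEG,
    CENTRAL_WIDTH_DEG,
    SOA_MS,
)

CONDITIONS = (
    ("parent", "face"),
    ("unfamiliar", "face"),
    ("parent", "nonface"),
    ("unfamiliar", "nonface"),
)

_CRITERIA = ("insufficient_fixation", "invalid_data", "premature", "wrong_direction")


def _in_central_aoi(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (np.abs(x) <= CENTRAL_WIDTH_DEG / 2) & (np.abs(y) <= CENTRAL_HEIGHT_DEG / 2)


def code_trial(
    stream: pd.DataFrame,
    trial,
    *,
    soa_ms: float = SOA_MS,
    sample_rate: float = 30.0,
    analysis_window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> dict:
    """Code one gaze stream into a trial record.

    ``stream`` holds time_ms, x_deg, y_deg samples covering the trial
    from central onset through lateral offset; ``trial`` is the matching
    schedule entry (needs ``distractor_side``).  Latency is reported at
    sample resolution (one video frame at 30 Hz).
    """
    t = np.asarray(stream["time_ms"], dtype=float)
    x = np.asarray(stream["x_deg"], dtype=float)
    y = np.asarray(stream["y_deg"], dtype=float)
    central = _in_central_aoi(x, y)

    pre = t < soa_ms
    central_fixation_prop = float(central[pre].mean()) if pre.any() else 0.0

    period = 1000.0 / sample_rate
    lo, hi = analysis_window_ms
    in_window = (t >= soa_ms) & (t <= soa_ms + hi)
    tw = t[in_window]
    data_valid = bool(
        len(tw) >= 2 and np.max(np.diff(tw)) <= 1.5 * period
    )

    post = t >= soa_ms
    departed = post & ~central
    shift_latency_ms = np.nan
    shift_direction = "none"
    if departed.any():
        k = int(np.argmax(departed))
        shift_latency_ms = float(t[k] - soa_ms)
        sign = 1.0 if trial["distractor_side"] == "right" else -1.0
        shift_direction = "toward_distractor" if x[k] * sign > 0 else "away"

    rec = {
        "central_fixation_prop": central_fixation_prop,
        "shift_latency_ms": shift_latency_ms,
        "shift_direction": shift_direction,
        "data_valid": data_valid,
    }
    for key in ("infant_id", "block", "trial_index", "stimulus_class",
                "identity", "expression", "distractor_side"):
        if key in trial:
            rec[key] = trial[key]
    return rec


def code_streams(records: list[dict], **kwargs) -> pd.DataFrame:
    """Code a list of gaze-stream records (as emitted by the simulator)."""
    rows = []
    for rec in records:
        stream = pd.DataFrame(
            rec["samples"], columns=["time_ms", "x_deg", "y_deg"]
        )
        rows.append(code_trial(stream, rec, **kwargs))
    return pd.DataFrame(rows)


def trial_validity(
    trials: pd.DataFrame,
    *,
    min_fixation: float = 0.75,
    premature_ms: float = ANALYSIS_WINDOW_MS[0],
) -> pd.DataFrame:
    """Apply inclusion criteria i-iv; returns valid flag and first failure.

    A shift starting at exactly ``premature_ms`` counts as premature
    (validity requires a strictly later start).
    """
    has_shift = trials["shift_direction"].ne("none") & trials["shift_latency_ms"].notna()
    fail = pd.DataFrame(
        {
            "insufficient_fixation": trials["central_fixation_prop"] < min_fixation,
            "invalid_data": ~trials["data_valid"].astype(bool),
            "premature": has_shift & (trials["shift_latency_ms"] <= premature_ms),
            "wrong_direction": has_shift & trials["shift_direction"].eq("away"),
        }
    )
    valid = ~fail.any(axis=1)
    reason = pd.Series("", index=trials.index, dtype=object)
    for crit in reversed(_CRITERIA):  # earlier criteria overwrite later ones
        reason[fail[crit]] = crit
    return pd.DataFrame({"valid": valid, "invalid_reason": reason}, index=trials.index)


def _disengaged(trials: pd.DataFrame, window=ANALYSIS_WINDOW_MS) -> pd.Series:
    lo, hi = window
    return (
        trials["shift_direction"].eq("toward_distractor")
        & (trials["shift_latency_ms"] > lo)
        & (trials["shift_latency_ms"] <= hi)
    )


def condition_scores(
    trials: pd.DataFrame,
    *,
    min_valid: int = 3,
    pooling: str = "split4",
    window=ANALYSIS_WINDOW_MS,
) -> pd.DataFrame:
    """Per-infant condition scores from coded trials (one or many infants).

    For each of the four identity x class conditions: the number of
    valid trials, the probability of no disengagement (exact count
    ratio), and the mean dwell time with no-disengagement trials entered
    at the 1000 ms cap.  Pooled face / non-face scores average the 0/1
    outcomes over all valid trials of that class.  ``included`` requires
    at least ``min_valid`` valid trials in every condition
    (``pooling='pooled2'`` applies the rule to the pooled face and
    non-face classes instead).
    """
    if pooling not in ("split4", "pooled2"):
        raise ValueError("pooling must be 'split4' or 'pooled2'")
    df = trials.copy()
    if "valid" not in df.columns:
        df = df.join(trial_validity(df))
    df["disengaged"] = _disengaged(df, window)
    hi = window[1]
    df["dwell_ms"] = np.where(
        df["disengaged"], np.minimum(df["shift_latency_ms"], hi), hi
    )
    v = df[df["valid"]].copy()
    v["no_disengage"] = (~v["disengaged"]).astype(float)

    infants = pd.Index(sorted(df["infant_id"].unique()), name="infant_id")
    out = pd.DataFrame(index=infants)

    def _wide(grouped, keys):
        agg = grouped.agg(
            n=("no_disengage", "size"),
            p=("no_disengage", "mean"),
            dwell=("dwell_ms", "mean"),
        )
        for key in keys:
            lvl = 1 if isinstance(key, str) else list(range(1, agg.index.nlevels))
            try:
                sub = agg.xs(key, level=lvl)
            except KeyError:
                sub = agg.iloc[:0].reset_index(drop=True)
            name = key if isinstance(key, str) else "_".join(key)
            out[f"n_valid_{name}"] = sub["n"].reindex(infants).fillna(0).astype(int)
            out[f"p_no_disengage_{name}"] = sub["p"].reindex(infants)
            out[f"mean_dwell_ms_{name}"] = sub["dwell"].reindex(infants)

    _wide(v.groupby(["infant_id", "identity", "stimulus_class"]), CONDITIONS)
    _wide(v.groupby(["infant_id", "stimulus_class"]), ("face", "nonface"))

    if pooling == "split4":
        cond_n = [out[f"n_valid_{i}_{c}"] for i, c in CONDITIONS]
    else:
        cond_n = [out["n_valid_face"], out["n_valid_nonface"]]
    out["included"] = np.logical_and.reduce([c >= min_valid for c in cond_n])
    return out.reset_index()
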