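"""Independent brute-force oracles used by the tests.

Deliberately naive implementations: minute-grid membership counting for
presence and word apportionment, exact sign-flip enumeration for the
paired Wilcoxon test, and a direct latent-model simulation for the
large-sample partial-correlation value.  They share no code with the
package paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

WINDOW_MIN = (7 * 60, 22 * 60)  # minutes of day


def _epoch_minutes(ts) -> int:
    return int(pd.Timestamp(ts).value // 60_000_000_000)


def minute_set(intervals: pd.DataFrame, window_min=WINDOW_MIN) -> set[int]:
    """All epoch minutes covered by [start, end) intervals, window-clipped."""
    lo, hi = window_min
    out: set[int] = set()
    for row in intervals.itertuples(index=False):
        for m in range(_epoch_minutes(row.start), _epoch_minutes(row.end)):
            if lo <= m % 1440 < hi:
                out.add(m)
    return out


def presence_hours_oracle(intervals: pd.DataFrame, window_min=WINDOW_MIN) -> float:
    return len(minute_set(intervals, window_min)) / 60.0


def word_frequency_oracle(
    segments: pd.DataFrame, presence: pd.DataFrame, channel: str,
    window_min=WINDOW_MIN,
) -> float | None:
    """Recording-day words/hour by per-minute membership counting."""
    pres_min = minute_set(presence, window_min)
    seg_minutes = []
    for row in segments.itertuples(index=False):
        m0 = _epoch_minutes(row.start)
        n_min = int(round(row.duration_s / 60.0))
        seg_minutes.append((m0, n_min, getattr(row, channel)))
    if not seg_minutes:
        return None
    rec_lo = min(m for m, _, _ in seg_minutes)
    rec_hi = max(m + n for m, n, _ in seg_minutes)
    denom_min = [m for m in pres_min if rec_lo <= m < rec_hi]
    if not denom_min:
        return None
    words = 0.0
    for m0, n_min, count in seg_minutes:
        per_min = count / n_min
        for m in range(m0, m0 + n_min):
            lo, hi = window_min
            if lo <= m % 1440 < hi and m in pres_min:
                words += per_min
    return words / (len(denom_min) / 60.0)


def exposure_oracle(
    infants: pd.DataFrame, diary: pd.DataFrame, segments: pd.DataFrame
) -> pd.DataFrame:
    """Full exposure chain by minute counting, including imputation."""
    rows = []
    for infant in infants["infant_id"]:
        d_i = diary[diary["infant_id"] == infant]
        s_i = segments[segments["infant_id"] == infant]
        for role, chan in (("mother", "female_words"), ("father", "male_words")):
            pres = d_i[d_i["parent_role"] == role]
            freq = word_frequency_oracle(s_i, pres, chan)
            rows.append(
                {
                    "infant_id": infant,
                    "parent_role": role,
                    "word_frequency": freq,
                    "presence_hours_14d": presence_hours_oracle(pres),
                }
            )
    tbl = pd.DataFrame(rows)

    meta = infants.set_index("infant_id")
    observed = tbl.dropna(subset=["word_frequency"])
    site_median = {}
    for (site, role), grp in observed.assign(
        site=observed["infant_id"].map(meta["site"])
    ).groupby(["site", "parent_role"]):
        site_median[(site, role)] = float(np.median(grp["word_frequency"]))
    co_twin = {}
    twin_col = meta["twin_pair_id"].fillna("").astype(str)
    for pid, grp in twin_col[twin_col != ""].groupby(twin_col):
        ids = list(grp.index)
        if len(ids) == 2:
            co_twin[ids[0]], co_twin[ids[1]] = ids[1], ids[0]
    obs_map = observed.set_index(["infant_id", "parent_role"])["word_frequency"]

    for i in tbl.index[tbl["word_frequency"].isna()]:
        infant, role = tbl.at[i, "infant_id"], tbl.at[i, "parent_role"]
        if role == "father" and bool(meta.at[infant, "single_parent"]):
            tbl.at[i, "word_frequency"] = 0.0
        elif (co_twin.get(infant), role) in obs_map.index:
            tbl.at[i, "word_frequency"] = obs_map[(co_twin[infant], role)]
        else:
            tbl.at[i, "word_frequency"] = site_median[(meta.at[infant, "site"], role)]
    tbl["exposure_words"] = tbl["word_frequency"] * tbl["presence_hours_14d"]
    return tbl


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided p by enumerating all 2^n sign assignments (no ties/zeros)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def condition_scores_oracle(valid_face_outcomes) -> float:
    """Mean of no-disengagement 0/1 outcomes, written the long way."""
    total = 0
    for o in valid_face_outcomes:
        total += 1 - int(o)
    return total / len(valid_face_outcomes)


def latent_model_rs_oracle(
    rho: float,
    *,
    n: int = 100_000,
    seed: int = 12345,
    trait_effect: float = 1.0,
    base_face: float = 0.55,
    base_nonface: float = 0.24,
    trials_per_class: int = 24,
    p_valid: float = 0.8,
) -> float:
    """Large-sample partial Spearman from the latent measurement model.

    Simulates the data-generating story directly: a standard-normal
    exposure score z, a trait correlated rho with z, binomially sampled
    face / non-face no-disengagement proportions over the valid trials,
    then the rank-partial correlation of z and the face score given the
    non-face score.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    t = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
    nv_f = rng.binomial(trials_per_class, p_valid, n).clip(min=1)
    nv_n = rng.binomial(trials_per_class, p_valid, n).clip(min=1)
    face = rng.binomial(nv_f, expit(logit(base_face) + trait_effect * t)) / nv_f
    nonface = rng.binomial(nv_n, base_nonface) / nv_n

    rz, rf, rn = rankdata(z), rankdata(face), rankdata(nonface)
    design = np.column_stack([np.ones(n), rn])
    ez = rz - design @ np.linalg.lstsq(design, rz, rcond=None)[0]
    ef = rf - design @ np.linalg.lstsq(design, rf, rcond=None)[0]
    return float(np.corrcoef(ez, ef)[0, 1])
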