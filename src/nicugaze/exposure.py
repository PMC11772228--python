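"""Exposure to the parents' speech.

The exposure composite for one parent is

    exposure_words = word_frequency * presence_hours_14d

where ``word_frequency`` (words/hour) is the parent's sex-channel word
count during their presence on the recording day divided by the hours
they were present, and ``presence_hours_14d`` is the diary presence over
the 14-day period.  Both factors use only the 07:00-22:00 active-care
window of each day.  Parents with no presence on the recording day get an
imputed frequency: a single-parent family's absent father contributes
zero; otherwise the co-twin's observed value if available; otherwise the
site median of observed frequencies for that role.

Intervals are half-open ``[start, end)`` at minute resolution, so
abutting intervals never double-count a boundary minute.  Words in a
segment that partially overlaps a presence interval are apportioned
proportionally to the overlap fraction of the segment's duration
(unbiased if words arrive uniformly within a segment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ROLES = ("mother", "father")
CHANNEL = {"mother": "female_words", "father": "male_words"}
DEFAULT_WINDOW = ("07:00", "22:00")


class ImputationError(ValueError):
    """No observed word frequencies available to impute from."""


def _window_timedeltas(window):
    lo = pd.Timedelta(window[0] + ":00")
    hi = pd.Timedelta(window[1] + ":00")
    if lo >= hi:
        raise ValueError("window start must precede window end within one day")
    return lo, hi


def clip_to_window(intervals: pd.DataFrame, window=DEFAULT_WINDOW) -> pd.DataFrame:
    """Clip presence intervals to a daily window, splitting midnight spans.

    ``intervals`` needs ``start`` and ``end`` datetime columns; other
    columns are carried through.  Rows whose clipped duration is zero are
    dropped.  Malformed rows (start >= end) raise with the row label.
    """
    df = intervals.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"interval start >= end at rows {list(bad[:5])}")
    lo, hi = _window_timedeltas(window)
    if df.empty:
        return df

    # split intervals at midnight boundaries, then clip each day's piece
    first_day = df["start"].dt.normalize()
    last_day = (df["end"] - pd.Timedelta("1ns")).dt.normalize()
    n_days = ((last_day - first_day).dt.days + 1).to_numpy()
    rep = df.loc[df.index.repeat(n_days)].reset_index(drop=True)
    day = (
        first_day.to_numpy().repeat(n_days)
        + np.concatenate([np.arange(k) for k in n_days]).astype("timedelta64[D]")
    )
    day = pd.Series(day, index=rep.index)
    win_lo = day + lo
    win_hi = day + hi
    start = rep["start"].clip(lower=win_lo)
    end = rep["end"].clip(upper=win_hi)
    keep = start < end
    rep = rep.loc[keep].copy()
    rep["start"] = start[keep]
    rep["end"] = end[keep]
    return rep.reset_index(drop=True)


def normalize_intervals(
    intervals: pd.DataFrame, by=("infant_id", "parent_role")
) -> pd.DataFrame:
    """Merge overlapping/abutting intervals within each group."""
    df = intervals.sort_values([*by, "start"], kind="stable").reset_index(drop=True)
    if df.empty:
        return df
    new_group = df[list(by)].ne(df[list(by)].shift()).any(axis=1)
    running_max = (
        df.groupby(new_group.cumsum())["end"].cummax().shift()
    )
    new_run = new_group | (df["start"] > running_max)
    run = new_run.cumsum()
    out = df.groupby(run).agg(
        {**{c: "first" for c in df.columns if c != "end"}, "end": "max"}
    )
    return out[list(df.columns)].reset_index(drop=True)


def presence_hours(
    intervals: pd.DataFrame, by=("infant_id", "parent_role")
) -> pd.Series:
    """Total interval duration in hours per group (empty group -> absent)."""
    if intervals.empty:
        return pd.Series(dtype=float, name="presence_hours")
    dur = (intervals["end"] - intervals["start"]).dt.total_seconds() / 3600.0
    return dur.groupby([intervals[c] for c in by]).sum().rename("presence_hours")


def _overlap_hours(seg_start, seg_end, iv_start, iv_end):
    lo = np.maximum(seg_start, iv_start)
    hi = np.minimum(seg_end, iv_end)
    return np.clip((hi - lo) / np.timedelta64(1, "h"), 0.0, None)


def observed_word_frequency(
    segments: pd.DataFrame,
    presence: pd.DataFrame,
    window=DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Recording-day word frequency (words/hour) per infant x parent role.

    ``segments``: infant_id, start, duration_s, female_words, male_words.
    ``presence``: diary rows for the recording day (any days are accepted;
    only those overlapping the segments count).  Both are clipped to the
    daily window.  Returns one row per (infant_id, parent_role) with
    ``word_frequency`` NaN when the parent had zero clipped presence
    during the recording — the imputation path.
    """
    seg = segments.copy()
    seg["start"] = pd.to_datetime(seg["start"])
    seg["end"] = seg["start"] + pd.to_timedelta(seg["duration_s"], unit="s")
    if (seg["duration_s"] <= 0).any():
        raise ValueError("segment duration must be positive")
    if (seg[["female_words", "male_words"]] < 0).to_numpy().any():
        raise ValueError("word counts must be non-negative")
    seg = clip_to_window(seg.rename(columns={"end": "end"}), window)
    seg["seg_hours_clipped"] = (
        (seg["end"] - seg["start"]).dt.total_seconds() / 3600.0
    )
    # apportionment uses the full segment duration as the denominator
    seg["seg_hours_full"] = seg["duration_s"] / 3600.0

    pres = clip_to_window(presence, window)
    pres = normalize_intervals(pres)

    # recording coverage per infant: the span of that infant's segments
    cov = seg.groupby("infant_id").agg(rec_start=("start", "min"), rec_end=("end", "max"))

    rows = []
    for infant, seg_i in seg.groupby("infant_id", sort=True):
        rec_lo, rec_hi = cov.loc[infant]
        pres_i = pres[pres["infant_id"] == infant]
        for role in ROLES:
            iv = pres_i[pres_i["parent_role"] == role]
            iv_start = np.maximum(iv["start"].to_numpy(), np.datetime64(rec_lo))
            iv_end = np.minimum(iv["end"].to_numpy(), np.datetime64(rec_hi))
            keep = iv_start < iv_end
            iv_start, iv_end = iv_start[keep], iv_end[keep]
            pres_h = float(((iv_end - iv_start) / np.timedelta64(1, "h")).sum())
            if pres_h <= 0:
                rows.append((infant, role, np.nan, 0.0))
                continue
            ov = _overlap_hours(
                seg_i["start"].to_numpy()[:, None],
                seg_i["end"].to_numpy()[:, None],
                iv_start[None, :],
                iv_end[None, :],
            ).sum(axis=1)
            w = ov / seg_i["seg_hours_full"].to_numpy()
            words = float((seg_i[CHANNEL[role]].to_numpy() * w).sum())
            rows.append((infant, role, words / pres_h, pres_h))
    return pd.DataFrame(
        rows,
        columns=["infant_id", "parent_role", "word_frequency", "recording_presence_h"],
    )


def impute_word_frequency(freq: pd.DataFrame, infants: pd.DataFrame) -> pd.DataFrame:
    """Fill absent recording-day word frequencies.

    Precedence for a parent with no observed frequency: (a) single-parent
    family and role=father -> 0; (b) the co-twin's observed value; (c) the
    site median of observed frequencies for that role.  Adds a
    ``frequency_source`` column (observed / single_parent_zero /
    twin_cosample / site_median).
    """
    meta = infants.set_index("infant_id")
    out = freq.copy()
    out["frequency_source"] = np.where(
        out["word_frequency"].notna(), "observed", ""
    )
    observed = out[out["frequency_source"] == "observed"]
    site_of = meta["site"]
    site_median = (
        observed.assign(site=observed["infant_id"].map(site_of))
        .groupby(["site", "parent_role"])["word_frequency"]
        .median()
    )
    twin_of = {}
    if "twin_pair_id" in meta.columns:
        pairs = meta[meta["twin_pair_id"].astype(str).str.len() > 0]
        for pid, grp in pairs.groupby("twin_pair_id"):
            ids = list(grp.index)
            if len(ids) == 2:
                twin_of[ids[0]], twin_of[ids[1]] = ids[1], ids[0]
    obs_lookup = observed.set_index(["infant_id", "parent_role"])["word_frequency"]

    for i in out.index[out["frequency_source"] == ""]:
        infant = out.at[i, "infant_id"]
        role = out.at[i, "parent_role"]
        if role == "father" and bool(meta.at[infant, "single_parent"]):
            out.at[i, "word_frequency"] = 0.0
            out.at[i, "frequency_source"] = "single_parent_zero"
            continue
        co = twin_of.get(infant)
        if co is not None and (co, role) in obs_lookup.index:
            out.at[i, "word_frequency"] = obs_lookup[(co, role)]
            out.at[i, "frequency_source"] = "twin_cosample"
            continue
        key = (site_of[infant], role)
        if key not in site_median.index or not np.isfinite(site_median[key]):
            raise ImputationError(
                f"no observed {role} word frequencies at site {key[0]}"
            )
        out.at[i, "word_frequency"] = site_median[key]
        out.at[i, "frequency_source"] = "site_median"
    return out


def compute_exposure(word_frequency, presence_hours_14d):
    """Exposure composite: words/hour x presence hours over the diary period."""
    wf = np.asarray(word_frequency, dtype=float)
    ph = np.asarray(presence_hours_14d, dtype=float)
    if (wf < 0).any() or (ph < 0).any():
        raise ValueError("word frequency and presence hours must be non-negative")
    return wf * ph


def exposure_table(
    infants: pd.DataFrame,
    diary: pd.DataFrame,
    segments: pd.DataFrame,
    window=DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-infant, per-parent exposure estimates plus a family total row.

    Runs the full chain: clip the diary to the daily window, sum 14-day
    presence per parent, estimate recording-day word frequencies, impute
    absences, and form the composite.  Returns rows with
    parent_role in {mother, father, total}.
    """
    diary = diary.copy()
    diary["start"] = pd.to_datetime(diary["start"])
    diary["end"] = pd.to_datetime(diary["end"])
    clipped = normalize_intervals(clip_to_window(diary, window))
    ph = presence_hours(clipped)

    freq = observed_word_frequency(segments, clipped, window)
    freq = impute_word_frequency(freq, infants)

    grid = pd.MultiIndex.from_product(
        [infants["infant_id"], ROLES], names=["infant_id", "parent_role"]
    )
    tbl = freq.set_index(["infant_id", "parent_role"]).reindex(grid).reset_index()
    missing = tbl["word_frequency"].isna()
    if missing.any():
        # infants with no segments at all: impute everything
        tbl = impute_word_frequency(tbl, infants)
    tbl["presence_hours_14d"] = (
        tbl.set_index(["infant_id", "parent_role"]).index.map(ph).to_numpy()
    )
    tbl["presence_hours_14d"] = tbl["presence_hours_14d"].fillna(0.0)
    tbl["exposure_words"] = compute_exposure(
        tbl["word_frequency"], tbl["presence_hours_14d"]
    )

    totals = (
        tbl.groupby("infant_id", sort=False)
        .agg(
            exposure_words=("exposure_words", "sum"),
            presence_hours_14d=("presence_hours_14d", "sum"),
        )
        .reset_index()
    )
    totals["parent_role"] = "total"
    totals["word_frequency"] = np.nan
    totals["frequency_source"] = "sum"
    totals["recording_presence_h"] = np.nan
    cols = [
        "infant_id",
        "parent_role",
        "word_frequency",
        "frequency_source",
        "recording_presence_h",
        "presence_hours_14d",
        "exposure_words",
    ]
    out = pd.concat([tbl[cols], totals[cols]], ignore_index=True)
    return out.sort_values(["infant_id", "parent_role"], kind="stable", ignore_index=True)
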