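"""Synthetic NICU cohort generator.

Emulates the four study inputs — an infant/covariate table, a 14-day
caregiver-presence diary, a 16-hour day of timestamped adult-word-count
segments (LENA-export-like), and coded eye-tracking trials (or raw 30 Hz
gaze streams) — for a two-site preterm cohort with twin pairs and a known
latent coupling between speech exposure and face preference.

The generative model, per infant:

* parents have latent word frequencies (log-normal, site- and
  role-specific medians) and daily presence-hour means; twins share a
  family, hence parents, and a family-level multiplicative random effect;
* the diary holds one presence interval per parent per day inside the
  07:00-22:00 active-care window; a configurable fraction of parents is
  absent on the recording day (more often fathers);
* word segments carry Poisson counts driven by the parent's frequency
  during their presence plus a modest background (staff speech) rate;
* a latent trait t is coupled to the within-site normal scores of log
  total true exposure with correlation ``rho_exposure_preference``
  (bivariate-normal copula), and raises the per-trial log-odds of *not*
  disengaging from faces by ``trait_effect`` per trait SD; non-face
  trials are unaffected;
* a fraction ``trial_invalid_rate`` of trials is spoiled by one of the
  four real-world failure modes (poor central fixation, unusable video,
  premature shift, shift away from the distractor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from . import schedule as sched
from .schedule import (
    ANALYSIS_WINDOW_MS,
    CENTRAL_HEIGHT_DEG,
    CENTRAL_WIDTH_DEG,
    DISTRACTOR_DURATION_MS,
    DISTRACTOR_ECCENTRICITY_DEG,
    N_TRIALS,
    SOA_MS,
)

ROLES = ("mother", "father")
CHANNEL = {"mother": "female_words", "father": "male_words"}
DAY_WINDOW = ("07:00", "22:00")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_word_freq():
    # median words/hour, sigma of log; site A is single-family-room-like,
    # site B open-bay-like (large site contrast in parental talk)
    return {
        "A": {"mother": (1100.0, 0.5), "father": (330.0, 0.7)},
        "B": {"mother": (230.0, 0.6), "father": (15.0, 1.2)},
    }


def _default_presence():
    # median daily presence hours, sigma of log (parent-level)
    return {
        "A": {"mother": (8.0, 0.35), "father": (4.2, 0.5)},
        "B": {"mother": (11.0, 0.35), "father": (0.9, 0.8)},
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort."""

    n_infants_per_site: tuple[int, int] = (25, 38)
    n_twin_pairs: int = 7
    rho_exposure_preference: float = 0.35
    site_word_freq_params: Mapping = field(default_factory=_default_word_freq)
    site_presence_params: Mapping = field(default_factory=_default_presence)
    p_parent_absent_recording_day: Mapping[str, float] = field(
        default_factory=lambda: {"mother": 0.02, "father": 0.2}
    )
    p_single_parent: float = 0.05
    base_no_disengage: Mapping[str, float] = field(
        default_factory=lambda: {"face": 0.55, "nonface": 0.24}
    )
    trait_effect: float = 1.0  # log-odds per trait SD, face trials only
    trial_invalid_rate: float = 0.2
    gaze_noise_sd: float = 0.5  # degrees visual angle
    sample_rate: float = 30.0  # Hz
    emit_gaze_streams: bool = False
    segment_minutes: int = 10
    background_word_rate: Mapping[str, float] = field(
        default_factory=lambda: {"female": 30.0, "male": 5.0}
    )
    family_effect_sd: float = 0.3  # family-level log-scale random effect
    daily_jitter_sd: float = 0.3  # day-to-day log-scale presence jitter
    latency_lognorm: tuple[float, float] = (np.log(400.0), 0.35)
    n_diary_days: int = 14
    recording_day: int = 7  # 0-based index into the diary days
    start_date: str = "2024-03-04"
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_single_parent,
            self.trial_invalid_rate,
            *self.p_parent_absent_recording_day.values(),
            *self.base_no_disengage.values(),
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not -1.0 <= self.rho_exposure_preference <= 1.0:
            raise ConfigError("rho_exposure_preference must lie in [-1, 1]")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.gaze_noise_sd < 0:
            raise ConfigError("gaze_noise_sd must be non-negative")
        if not 0 <= self.recording_day < self.n_diary_days:
            raise ConfigError("recording_day must fall within the diary period")
        for site_params in self.site_word_freq_params.values():
            for med, sig in site_params.values():
                if med < 0 or sig <= 0:
                    raise ConfigError("word-frequency parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["latency_lognorm"] = list(self.latency_lognorm)
        return d


@dataclass
class CohortTables:
    """Bundle of synthetic study inputs plus the injected ground truth."""

    infants: pd.DataFrame
    diary: pd.DataFrame
    segments: pd.DataFrame
    trials: pd.DataFrame | None
    gaze_streams: list[dict] | None
    ground_truth: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.infants.to_csv(out / "infants.csv", index=False)
        self.diary.to_csv(out / "diary.csv", index=False)
        self.segments.to_csv(out / "lena_segments.csv", index=False)
        if self.trials is not None:
            self.trials.to_csv(out / "trials.csv", index=False)
        if self.gaze_streams is not None:
            with open(out / "gaze_streams.jsonl", "w") as fh:
                for rec in self.gaze_streams:
                    fh.write(json.dumps(rec) + "\n")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def _normal_scores_by_group(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Blom-type normal scores of ``values`` within each group."""
    out = np.empty_like(values, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        v = values[m]
        ranks = np.argsort(np.argsort(v)) + 1.0
        out[m] = ndtri((ranks - 0.5) / len(v))
    return out


def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    """Exact inverse-CDF sampling of a log-normal truncated to (lo, hi]."""
    from scipy.stats import norm

    a = norm.cdf((np.log(lo) - mu) / sigma)
    b = norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Draw a complete synthetic cohort; bit-identical under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = list(config.site_word_freq_params)
    n_a, n_b = config.n_infants_per_site
    n = n_a + n_b

    # --- families: twins first within each site ------------------------
    pairs_a = int(round(config.n_twin_pairs * n_a / max(n, 1)))
    pairs_a = min(pairs_a, n_a // 2)
    pairs_b = min(config.n_twin_pairs - pairs_a, n_b // 2)
    if pairs_a + pairs_b != config.n_twin_pairs:
        raise ConfigError("too many twin pairs for the cohort size")

    site = np.array([sites[0]] * n_a + [sites[1]] * n_b)
    twin_pair = np.full(n, "", dtype=object)
    family = np.empty(n, dtype=object)
    pair_id = 0
    fam_id = 0
    idx = 0
    for s, n_s, k_s in ((sites[0], n_a, pairs_a), (sites[1], n_b, pairs_b)):
        for _ in range(k_s):
            pid = f"tw{pair_id:02d}"
            for _ in range(2):
                twin_pair[idx] = pid
                family[idx] = f"fam{fam_id:03d}"
                idx += 1
            pair_id += 1
            fam_id += 1
        for _ in range(n_s - 2 * k_s):
            family[idx] = f"fam{fam_id:03d}"
            idx += 1
            fam_id += 1

    infant_id = np.array([f"inf{i:03d}" for i in range(n)])
    families, fam_index = np.unique(family, return_inverse=True)
    n_fam = len(families)
    fam_site = np.empty(n_fam, dtype=object)
    fam_site[fam_index] = site  # same site for both twins

    # --- covariates (shared within a family where biology dictates) ----
    ga_fam = np.clip(rng.normal(28.2, 2.0, n_fam), 23.5, 31.9)
    ga = ga_fam[fam_index]
    bw = np.clip(rng.normal(1074 + 200 * (ga - 28.0), 150.0), 400, None)
    sex = np.where(rng.random(n) < 0.6, "male", "female")
    deliv_fam = np.where(rng.random(n_fam) < 0.57, "cesarean", "vaginal")
    edu_fam = rng.choice(np.arange(1, 5), size=n_fam, p=[0.15, 0.25, 0.2, 0.4])
    single_fam = rng.random(n_fam) < config.p_single_parent

    # --- family-level parent parameters ---------------------------------
    fam_effect = rng.normal(0.0, config.family_effect_sd, n_fam)
    freq = {}
    daily_mean = {}
    for role in ROLES:
        med_sig_f = np.array(
            [config.site_word_freq_params[s][role] for s in fam_site]
        )
        freq[role] = np.exp(
            np.log(med_sig_f[:, 0])
            + med_sig_f[:, 1] * rng.normal(size=n_fam)
            + fam_effect
        )
        med_sig_p = np.array([config.site_presence_params[s][role] for s in fam_site])
        daily_mean[role] = np.exp(
            np.log(med_sig_p[:, 0])
            + med_sig_p[:, 1] * rng.normal(size=n_fam)
            + fam_effect
        )

    infants = pd.DataFrame(
        {
            "infant_id": infant_id,
            "site": site,
            "twin_pair_id": twin_pair,
            "family_id": family,
            "single_parent": single_fam[fam_index],
            "sex": sex,
            "gestational_age_wk": np.round(ga, 2),
            "birth_weight_g": np.round(bw, 0),
            "delivery_type": deliv_fam[fam_index],
            "maternal_education": edu_fam[fam_index],
        }
    )

    # --- diary: one interval per (infant, parent, day) ------------------
    base = pd.Timestamp(config.start_date)
    n_days = config.n_diary_days
    absent = {
        role: rng.random(n) < config.p_parent_absent_recording_day[role]
        for role in ROLES
    }
    diary_rows = []
    presence_14d = {role: np.zeros(n) for role in ROLES}
    rec_presence = {role: [] for role in ROLES}  # recording-day (start_h, end_h)
    for role in ROLES:
        has_parent = np.ones(n, dtype=bool)
        if role == "father":
            has_parent = ~single_fam[fam_index]
        mean_h = daily_mean[role][fam_index]
        hours = mean_h[:, None] * np.exp(
            rng.normal(0.0, config.daily_jitter_sd, (n, n_days))
        )
        hours = np.clip(hours, 0.0, 13.0)
        hours[~has_parent, :] = 0.0
        hours[absent[role], config.recording_day] = 0.0
        # diary resolution is one minute: work in integer minutes throughout
        dur_min = np.round(hours * 60.0).astype(int)
        start_h = 7.0 + rng.random((n, n_days)) * np.maximum(15.0 - dur_min / 60.0, 0.0)
        start_min = np.round(start_h * 60.0).astype(int)
        presence_14d[role] = dur_min.sum(axis=1) / 60.0
        for i in range(n):
            for d in range(n_days):
                m = dur_min[i, d]
                if m <= 0:
                    continue
                t0 = base + pd.Timedelta(days=d, minutes=int(start_min[i, d]))
                diary_rows.append(
                    (infant_id[i], role, t0, t0 + pd.Timedelta(minutes=int(m)),
                     "present")
                )
        rd = config.recording_day
        rec = np.stack([start_min[:, rd] / 60.0,
                        (start_min[:, rd] + dur_min[:, rd]) / 60.0], axis=1)
        rec[dur_min[:, rd] <= 0] = np.nan
        rec_presence[role] = rec
    diary = pd.DataFrame(
        diary_rows, columns=["infant_id", "parent_role", "start", "end", "modality"]
    ).sort_values(["infant_id", "parent_role", "start"], kind="stable", ignore_index=True)

    # --- LENA segments on the recording day ------------------------------
    seg_min = config.segment_minutes
    rec_day = base + pd.Timedelta(days=config.recording_day)
    rec_start_min = 360 + np.round(rng.random(n) * 60.0).astype(int)  # 06:00-07:00
    rec_start_h = rec_start_min / 60.0
    n_seg = int(np.ceil(16 * 60 / seg_min))
    offsets = np.arange(n_seg) * seg_min / 60.0  # hours
    seg_start_h = rec_start_h[:, None] + offsets[None, :]
    seg_end_h = seg_start_h + seg_min / 60.0
    seg_hours = seg_min / 60.0
    counts = {}
    for role, chan in CHANNEL.items():
        iv = rec_presence[role]
        lo = np.where(np.isnan(iv[:, 0]), 0.0, iv[:, 0])[:, None]
        hi = np.where(np.isnan(iv[:, 1]), 0.0, iv[:, 1])[:, None]
        overlap = np.clip(np.minimum(seg_end_h, hi) - np.maximum(seg_start_h, lo), 0.0, None)
        bg = config.background_word_rate["female" if chan == "female_words" else "male"]
        lam = freq[role][fam_index][:, None] * overlap + bg * seg_hours
        counts[chan] = rng.poisson(lam)
    segments = pd.DataFrame(
        {
            "infant_id": np.repeat(infant_id, n_seg),
            "start": rec_day
            + pd.to_timedelta(
                (rec_start_min[:, None] + np.arange(n_seg) * seg_min).ravel(),
                unit="m",
            ),
            "duration_s": np.full(n * n_seg, seg_min * 60.0),
            "female_words": counts["female_words"].ravel(),
            "male_words": counts["male_words"].ravel(),
        }
    )

    # --- latent trait coupled to log total true exposure -----------------
    true_exposure = {
        role: freq[role][fam_index] * presence_14d[role] for role in ROLES
    }
    total_true = true_exposure["mother"] + true_exposure["father"]
    z_e = _normal_scores_by_group(np.log(np.maximum(total_true, 1.0)), site)
    rho = config.rho_exposure_preference
    trait = rho * z_e + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n)

    # --- trials -----------------------------------------------------------
    cls, identity, expr, side = sched._schedule_arrays(rng, n)
    is_face = cls == "face"
    p_nd = np.where(
        is_face,
        expit(logit(config.base_no_disengage["face"]) + config.trait_effect * trait[:, None]),
        config.base_no_disengage["nonface"],
    )
    disengage = rng.random((n, N_TRIALS)) < (1.0 - p_nd)
    lo_ms, hi_ms = ANALYSIS_WINDOW_MS
    mu_l, sig_l = config.latency_lognorm
    latency = _truncated_lognormal(rng, mu_l, sig_l, lo_ms + 1e-9, hi_ms, (n, N_TRIALS))

    invalid = rng.random((n, N_TRIALS)) < config.trial_invalid_rate
    mechanism = rng.integers(0, 4, (n, N_TRIALS))  # fixation/data/premature/away

    cfp = rng.uniform(0.80, 1.0, (n, N_TRIALS))
    data_valid = np.ones((n, N_TRIALS), dtype=bool)
    shift_lat = np.where(disengage, latency, np.nan)
    shift_dir = np.where(disengage, "toward_distractor", "none").astype(object)

    m = invalid & (mechanism == 0)
    cfp[m] = rng.uniform(0.0, 0.75, m.sum())
    m = invalid & (mechanism == 1)
    data_valid[m] = False
    m = invalid & (mechanism == 2)  # premature shift
    shift_lat[m] = rng.uniform(30.0, lo_ms, m.sum())
    shift_dir[m] = "toward_distractor"
    m = invalid & (mechanism == 3)  # shift away from the distractor
    shift_lat[m] = rng.uniform(200.0, 900.0, m.sum())
    shift_dir[m] = "away"

    trials = pd.DataFrame(
        {
            "infant_id": np.repeat(infant_id, N_TRIALS),
            "block": np.tile(np.repeat(np.arange(1, 5), 12), n),
            "trial_index": np.tile(np.arange(1, N_TRIALS + 1), n),
            "stimulus_class": cls.ravel(),
            "identity": identity.ravel(),
            "expression": expr.ravel(),
            "distractor_side": side.ravel(),
            "central_fixation_prop": np.round(cfp.ravel(), 4),
            "shift_latency_ms": np.round(shift_lat.ravel(), 3),
            "shift_direction": shift_dir.ravel(),
            "data_valid": data_valid.ravel(),
        }
    )

    gaze_streams = None
    trials_out: pd.DataFrame | None = trials
    if config.emit_gaze_streams:
        gaze_streams = _streams_from_trials(trials, config, rng)
        trials_out = None

    ground_truth = {
        "config": _jsonable(config.to_dict()),
        "trait": dict(zip(infant_id.tolist(), np.round(trait, 6).tolist())),
        "true_exposure_total": dict(
            zip(infant_id.tolist(), np.round(total_true, 3).tolist())
        ),
        "true_word_frequency": {
            role: dict(
                zip(infant_id.tolist(), np.round(freq[role][fam_index], 3).tolist())
            )
            for role in ROLES
        },
        "parent_absent_recording_day": {
            role: infant_id[absent[role]].tolist() for role in ROLES
        },
    }
    return CohortTables(infants, diary, segments, trials_out, gaze_streams, ground_truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def simulate_gaze_stream(
    trial: Mapping,
    disengage: bool,
    latency_ms: float | None = None,
    *,
    sample_rate: float = 30.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    soa_ms: float = SOA_MS,
    distractor_duration_ms: float = DISTRACTOR_DURATION_MS,
    shift_direction: str = "toward_distractor",
    central_fixation_prop: float = 1.0,
    drop_analysis_samples: bool = False,
) -> pd.DataFrame:
    """Render one trial as a 30 Hz (by default) gaze-sample stream.

    Gaze sits on the central stimulus until ``soa_ms + latency_ms``, then
    jumps to the distractor location (~12 deg on the cued side) when
    ``disengage`` is true.  Gaussian positional noise of ``noise_sd``
    degrees is added to every sample.  On a noise-free stream the trial
    coder recovers the injected outcome and latency to within one sample
    period (round-trip guarantee).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if disengage and not (0.0 < latency_ms < distractor_duration_ms):
        raise ValueError("latency_ms must lie within (0, distractor duration)")
    period = 1000.0 / sample_rate
    t_end = soa_ms + distractor_duration_ms
    times = np.arange(0.0, t_end, period)
    x = np.zeros_like(times)
    y = np.zeros_like(times)
    ecc = DISTRACTOR_ECCENTRICITY_DEG
    sign = 1.0 if trial["distractor_side"] == "right" else -1.0
    if disengage:
        shifted = times >= soa_ms + latency_ms
        if shift_direction == "toward_distractor":
            x[shifted] = sign * ecc
        else:
            x[shifted] = -sign * ecc
    if central_fixation_prop < 1.0:
        # gaze off-centre for part of the pre-lateral period (tail end)
        pre = times < soa_ms
        n_off = int(round((1.0 - central_fixation_prop) * pre.sum()))
        if n_off > 0:
            off_idx = np.where(pre)[0][:n_off]
            y[off_idx] = CENTRAL_HEIGHT_DEG  # well outside the central AOI
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.shape)
        y = y + rng.normal(0.0, noise_sd, y.shape)
    stream = pd.DataFrame({"time_ms": times, "x_deg": x, "y_deg": y})
    if drop_analysis_samples:
        # knock a hole in the analysis window so the coder flags the video
        bad = (stream["time_ms"] > soa_ms + 300) & (stream["time_ms"] < soa_ms + 500)
        stream = stream.loc[~bad].reset_index(drop=True)
    return stream


def _streams_from_trials(
    trials: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    """Render every simulated trial outcome as a gaze stream record."""
    out = []
    for row in trials.itertuples(index=False):
        disengage = row.shift_direction != "none" and np.isfinite(row.shift_latency_ms)
        stream = simulate_gaze_stream(
            {"distractor_side": row.distractor_side},
            disengage,
            row.shift_latency_ms if disengage else None,
            sample_rate=config.sample_rate,
            noise_sd=config.gaze_noise_sd,
            rng=rng,
            shift_direction=row.shift_direction if disengage else "toward_distractor",
            central_fixation_prop=row.central_fixation_prop,
            drop_analysis_samples=not row.data_valid,
        )
        out.append(
            {
                "infant_id": row.infant_id,
                "trial_index": int(row.trial_index),
                "block": int(row.block),
                "stimulus_class": row.stimulus_class,
                "identity": row.identity,
                "expression": row.expression,
                "distractor_side": row.distractor_side,
                "samples": np.round(
                    stream[["time_ms", "x_deg", "y_deg"]].to_numpy(), 4
                ).tolist(),
            }
        )
    return out
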