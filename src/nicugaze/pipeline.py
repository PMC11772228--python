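"""End-to-end pipeline: inputs -> exposure -> scores -> statistics -> report.

Consumes either the four real-style input tables (infants, presence
diary, word segments, coded trials or gaze streams) or a simulation
block, and produces exposure.csv, scores.csv, results.json and a
markdown report structured like a results section: descriptives, site
exposure medians, the face vs non-face test, adjusted correlations, and
the twin-subset sensitivity analysis.  Every stage is a pure function of
its inputs plus the seed, so a re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure as expo
from . import gaze, stats
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("nicugaze")

DEFAULT_COVARIATES = (
    "gestational_age_wk",
    "maternal_education",
    "delivery_code",
    "sex_code",
    "birth_weight_g",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Inputs plus analysis options for one pipeline run."""

    simulation: SimulationConfig | None = None
    infants_path: str | None = None
    diary_path: str | None = None
    segments_path: str | None = None
    trials_path: str | None = None
    gaze_streams_path: str | None = None
    window: tuple[str, str] = expo.DEFAULT_WINDOW
    min_valid_trials: int = 3
    pooling: str = "split4"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    bootstrap_reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        have_paths = all(
            p is not None for p in (self.infants_path, self.diary_path, self.segments_path)
        ) and (self.trials_path is not None or self.gaze_streams_path is not None)
        if self.simulation is None and not have_paths:
            raise ValueError(
                "provide either a simulation block or all four input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None, **raw
        )
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        return cohort.infants, cohort.diary, cohort.segments, cohort.trials, cohort.gaze_streams
    infants = pd.read_csv(config.infants_path)
    diary = pd.read_csv(config.diary_path, parse_dates=["start", "end"])
    segments = pd.read_csv(config.segments_path, parse_dates=["start"])
    trials = streams = None
    if config.trials_path is not None:
        trials = pd.read_csv(config.trials_path)
    else:
        streams = [
            json.loads(line)
            for line in Path(config.gaze_streams_path).read_text().splitlines()
            if line.strip()
        ]
    return infants, diary, segments, trials, streams


def _code_values(infants: pd.DataFrame) -> pd.DataFrame:
    df = infants.copy()
    df["delivery_code"] = (df["delivery_type"] == "cesarean").astype(int)
    df["sex_code"] = (df["sex"] == "male").astype(int)
    return df


def build_analysis_frame(
    infants: pd.DataFrame, exposure_tbl: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """One row per included infant with exposures, scores and covariates."""
    wide = exposure_tbl.pivot(
        index="infant_id", columns="parent_role", values="exposure_words"
    )
    wide.columns = [f"exposure_{c}" for c in wide.columns]
    df = _code_values(infants).merge(wide, on="infant_id")
    df = df.merge(scores, on="infant_id", how="inner")
    return df


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis; optionally write all artifacts to out_dir."""
    infants, diary, segments, trials, streams = _load_inputs(config)
    log.info("inputs: %d infants, %d diary rows, %d segments",
             len(infants), len(diary), len(segments))

    if trials is None:
        trials = gaze.code_streams(streams)
        log.info("coded %d gaze streams", len(trials))

    exposure_tbl = expo.exposure_table(infants, diary, segments, window=config.window)
    src_counts = (
        exposure_tbl[exposure_tbl["parent_role"] != "total"]["frequency_source"]
        .value_counts()
        .to_dict()
    )
    log.info("imputation sources: %s", src_counts)

    judged = trials.join(gaze.trial_validity(trials))
    scores = gaze.condition_scores(
        judged, min_valid=config.min_valid_trials, pooling=config.pooling
    )
    n_excluded = int((~scores["included"]).sum())
    log.info("%d infants excluded by the valid-trial rule", n_excluded)
    included = scores[scores["included"]]
    if included.empty:
        raise PipelineError("no included infants")

    frame = build_analysis_frame(infants, exposure_tbl, included)
    reps = config.bootstrap_reps
    seed = config.seed

    results: dict = {
        "n_infants": int(len(infants)),
        "n_included": int(len(frame)),
        "n_excluded_valid_trial_rule": n_excluded,
        "imputation_sources": {k: int(v) for k, v in sorted(src_counts.items())},
        "descriptives": _descriptives(infants, exposure_tbl, frame),
    }

    wil = stats.wilcoxon_paired(
        frame["p_no_disengage_face"], frame["p_no_disengage_nonface"]
    )
    results["face_vs_nonface"] = {
        "mean_face": float(frame["p_no_disengage_face"].mean()),
        "sd_face": float(frame["p_no_disengage_face"].std(ddof=1)),
        "mean_nonface": float(frame["p_no_disengage_nonface"].mean()),
        "sd_nonface": float(frame["p_no_disengage_nonface"].std(ddof=1)),
        **wil.to_dict(),
    }

    pf = frame.dropna(
        subset=["p_no_disengage_parent_face", "p_no_disengage_unfamiliar_face"]
    )
    try:
        wil_pf = stats.wilcoxon_paired(
            pf["p_no_disengage_parent_face"], pf["p_no_disengage_unfamiliar_face"]
        )
        results["parent_vs_unfamiliar_face"] = {
            "mean_parent": float(pf["p_no_disengage_parent_face"].mean()),
            "mean_unfamiliar": float(pf["p_no_disengage_unfamiliar_face"].mean()),
            **wil_pf.to_dict(),
        }
    except stats.DegenerateDataError:
        results["parent_vs_unfamiliar_face"] = {"degenerate": True}

    for label, col in (
        ("total", "exposure_total"),
        ("mother", "exposure_mother"),
        ("father", "exposure_father"),
    ):
        res = stats.adjusted_association(
            frame, exposure_col=col, ci_reps=reps, seed=seed
        )
        results[f"face_preference_vs_exposure_{label}"] = res.to_dict()

    res_adj = stats.adjusted_association(
        frame,
        exposure_col="exposure_total",
        covariate_cols=config.covariates,
        ci_reps=reps,
        seed=seed,
    )
    results["face_preference_vs_exposure_total_covariate_adjusted"] = res_adj.to_dict()

    res_parent = stats.adjusted_association(
        frame,
        exposure_col="exposure_total",
        face_col="p_no_disengage_parent_face",
        nonface_col="p_no_disengage_unfamiliar_face",
        ci_reps=reps,
        seed=seed,
    )
    results["parent_face_preference_vs_exposure_total"] = res_parent.to_dict()

    def _subset_rs(subset: pd.DataFrame) -> float:
        return stats.adjusted_association(
            subset, exposure_col="exposure_total", ci_reps=0
        ).estimate

    twin_raw = frame["twin_pair_id"].fillna("").astype(str)
    twin_ids = twin_raw.where(twin_raw.str.len() > 0)
    # pairs with only one retained member count as singletons
    counts = twin_ids.value_counts()
    twin_ids = twin_ids.where(twin_ids.map(counts).eq(2))
    sens = stats.twin_subset_sensitivity(frame, twin_ids, _subset_rs)
    results["twin_subset_sensitivity"] = sens.to_dict()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        exposure_tbl.to_csv(out / "exposure.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        (out / "results.json").write_bytes(
            json.dumps(results, indent=1, sort_keys=True).encode()
        )
        (out / "report.md").write_text(render_report(results))
    return results


def _descriptives(infants, exposure_tbl, frame) -> dict:
    e = exposure_tbl.merge(infants[["infant_id", "site"]], on="infant_id")
    obs = e[e["frequency_source"] == "observed"]
    d: dict = {"n_per_site": infants["site"].value_counts().sort_index().to_dict()}
    d["median_word_frequency_observed"] = {
        f"{site}_{role}": float(g["word_frequency"].median())
        for (site, role), g in obs.groupby(["site", "parent_role"])
    }
    parents = e[e["parent_role"] != "total"]
    d["median_presence_hours_14d"] = {
        f"{site}_{role}": float(g["presence_hours_14d"].median())
        for (site, role), g in parents.groupby(["site", "parent_role"])
    }
    d["median_exposure_words"] = {
        f"{site}_{role}": float(g["exposure_words"].median())
        for (site, role), g in e.groupby(["site", "parent_role"])
    }
    d["median_valid_trials_face"] = float(frame["n_valid_face"].median())
    d["median_valid_trials_nonface"] = float(frame["n_valid_nonface"].median())
    return d


def render_report(results: dict) -> str:
    """Plain-markdown report mirroring a results-section structure."""
    r = results
    fv = r["face_vs_nonface"]
    lines = [
        "# Speech exposure and face preference — pipeline report",
        "",
        "## Cohort",
        f"- infants: {r['n_infants']}, included after the valid-trial rule: "
        f"{r['n_included']} (excluded: {r['n_excluded_valid_trial_rule']})",
        f"- word-frequency imputation sources: {r['imputation_sources']}",
        "",
        "## Exposure by site (medians)",
    ]
    for key, val in r["descriptives"]["median_exposure_words"].items():
        lines.append(f"- exposure {key}: {val:,.0f} words / 14 days")
    lines += [
        "",
        "## Face preference",
        f"- P(no disengagement) faces: M={fv['mean_face']:.2f} (SD {fv['sd_face']:.2f}) "
        f"vs non-faces: M={fv['mean_nonface']:.2f} (SD {fv['sd_nonface']:.2f}); "
        f"z={fv['z']:.2f}, p={fv['p_value']:.2g}, effect size z/sqrt(N)="
        f"{fv['effect_size']:.2f}",
        "",
        "## Exposure-preference correlations (per-site z-scored, partial Spearman)",
    ]
    for label in ("total", "mother", "father"):
        a = r[f"face_preference_vs_exposure_{label}"]
        lines.append(
            f"- {label} exposure vs face score | non-face score: "
            f"r_s={a['estimate']:.2f} [{a['ci_low']:.2f}, {a['ci_high']:.2f}], "
            f"p={a['p_value']:.3f}, n={a['n']}"
        )
    a = r["face_preference_vs_exposure_total_covariate_adjusted"]
    lines.append(
        f"- covariate-adjusted (GA, education, delivery, sex, birth weight): "
        f"r_s={a['estimate']:.2f} [{a['ci_low']:.2f}, {a['ci_high']:.2f}], "
        f"p={a['p_value']:.3f}"
    )
    a = r["parent_face_preference_vs_exposure_total"]
    lines += [
        "",
        "## Parent-face preference",
        f"- exposure vs parent-face score | unfamiliar-face score: "
        f"r_s={a['estimate']:.2f} [{a['ci_low']:.2f}, {a['ci_high']:.2f}], "
        f"p={a['p_value']:.3f}",
    ]
    s = r["twin_subset_sensitivity"]
    lines += [
        "",
        "## Twin-subset sensitivity",
        f"- {s['n_subsets']} subsets (one infant per twin pair): r_s range "
        f"{s['min']:.2f}-{s['max']:.2f}, median {s['median']:.2f}",
        "",
    ]
    return "\n".join(lines)
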