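"""Rank-based statistical layer.

Implements the analyses used on the cohort: paired Wilcoxon signed-rank
tests with the z/sqrt(N) effect size, per-site z-scoring, partial
Spearman rank correlations (rank-transform everything, residualize the
two variables of interest on the ranked covariates by least squares,
correlate the residuals), and an exhaustive twin-subset sensitivity
analysis that reruns an analysis on every way of keeping one infant per
twin pair.

The partial Spearman here is the classical rank-then-residualize
("rank-Pearson partial") estimator — deterministic and closed-form; with
an empty covariate set it reduces exactly to the ordinary Spearman
coefficient.  Confidence intervals are bootstrap percentile intervals
over infants (seeded); p-values use the t approximation with
df = n - 2 - #covariates.  Ties get average ranks throughout; zero
differences in the Wilcoxon test are dropped.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on these data."""


@dataclass
class AnalysisResult:
    statistic_name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    adjustment_set: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "adjustment_set": list(self.adjustment_set),
        }
        d.update(self.extra)
        return d


@dataclass
class SubsetSensitivityResult:
    n_subsets: int
    r_s_values: np.ndarray
    min: float
    max: float
    median: float

    def to_dict(self) -> dict:
        return {
            "n_subsets": self.n_subsets,
            "min": self.min,
            "max": self.max,
            "median": self.median,
            "r_s_values": np.asarray(self.r_s_values, dtype=float).tolist(),
        }


def zscore_by_site(values, site_labels) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 within each site."""
    x = np.asarray(values, dtype=float)
    sites = np.asarray(site_labels)
    out = np.empty_like(x)
    for s in np.unique(sites):
        m = sites == s
        if m.sum() < 2:
            raise DegenerateDataError(f"site {s!r} has fewer than 2 values")
        sd = np.std(x[m], ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDataError(f"site {s!r} has constant values")
        out[m] = (x[m] - np.mean(x[m])) / sd
    return out


def wilcoxon_paired(x, y, *, exact_max_n: int = 25) -> AnalysisResult:
    """Paired Wilcoxon signed-rank test with the z/sqrt(N) effect size.

    Zero differences are dropped (N counts the retained pairs) and tied
    absolute differences get average ranks.  The p-value comes from the
    exact sign-flip distribution when there are no zeros or ties and
    N <= ``exact_max_n``, otherwise from the normal approximation (no
    continuity correction); z is always the approximation's statistic, so
    the effect size |z|/sqrt(N) is defined in both regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d_nz = d[d != 0]
    n_eff = len(d_nz)
    if n_eff == 0:
        raise DegenerateDataError("all pairwise differences are zero")
    approx = sps.wilcoxon(x, y, zero_method="wilcox", correction=False, method="approx")
    z = float(approx.zstatistic)
    has_ties = len(np.unique(np.abs(d_nz))) < n_eff
    if not has_ties and n_eff <= exact_max_n:
        p = float(sps.wilcoxon(x, y, zero_method="wilcox", method="exact").pvalue)
    else:
        p = float(approx.pvalue)
    effect = abs(z) / np.sqrt(n_eff)
    return AnalysisResult(
        statistic_name="wilcoxon_signed_rank",
        estimate=effect,
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=p,
        n=n_eff,
        extra={"z": z, "W": float(approx.statistic), "effect_size": effect},
    )


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=0)


def _partial_corr_of_ranks(rx, ry, rc) -> float:
    if rc.shape[1]:
        design = np.column_stack([np.ones(len(rx)), rc])
        bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
        by, *_ = np.linalg.lstsq(design, ry, rcond=None)
        ex = rx - design @ bx
        ey = ry - design @ by
    else:
        ex = rx - rx.mean()
        ey = ry - ry.mean()
    sx = np.sqrt((ex**2).sum())
    sy = np.sqrt((ey**2).sum())
    # residuals that vanish to numerical noise (e.g. y adjusted on itself)
    # leave the correlation undefined
    tol = 1e-8 * max(
        np.sqrt(((rx - rx.mean()) ** 2).sum()),
        np.sqrt(((ry - ry.mean()) ** 2).sum()),
        1.0,
    )
    if sx <= tol or sy <= tol:
        raise DegenerateDataError("a variable is constant after rank adjustment")
    return float((ex * ey).sum() / (sx * sy))


def spearman_partial(
    x,
    y,
    covariates=None,
    *,
    ci_reps: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
    covariate_names: tuple[str, ...] = (),
) -> AnalysisResult:
    """Partial Spearman rank correlation of x and y given covariates.

    All variables are rank-transformed (average ranks); x and y are
    residualized on the ranked covariates (with intercept) by least
    squares, and the residuals are Pearson-correlated.  With no
    covariates this equals the ordinary Spearman coefficient.  Constant
    covariates are dropped with a warning.  CI: seeded bootstrap
    percentile over rows (re-ranked within each resample);
    ``ci_reps=0`` skips it.  p-value: t approximation with
    df = n - 2 - #covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = []
    for j in range(cov.shape[1]):
        if np.ptp(cov[:, j]) == 0:
            name = covariate_names[j] if j < len(covariate_names) else f"cov{j}"
            warnings.warn(
                f"covariate {name!r} is constant and was dropped", stacklevel=2
            )
        else:
            keep.append(j)
    cov = cov[:, keep]
    n = len(x)
    k = cov.shape[1]
    if n <= k + 2:
        raise DegenerateDataError("need n > #covariates + 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("x or y is constant")

    rx, ry = _rank(x), _rank(y)
    rc = _rank(cov) if k else cov
    r = _partial_corr_of_ranks(rx, ry, rc)

    df = n - 2 - k
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))

    ci_low = ci_high = np.nan
    if ci_reps:
        rng = np.random.default_rng(seed)
        boots = np.empty(ci_reps)
        data = np.column_stack([x, y, cov])
        for b in range(ci_reps):
            idx = rng.integers(0, n, n)
            d = data[idx]
            try:
                boots[b] = _partial_corr_of_ranks(
                    _rank(d[:, 0]), _rank(d[:, 1]), _rank(d[:, 2:]) if k else d[:, 2:]
                )
            except DegenerateDataError:
                boots[b] = np.nan
        ci_low, ci_high = np.nanpercentile(
            boots, [100 * alpha / 2, 100 * (1 - alpha / 2)]
        )
    names = tuple(
        covariate_names[j] if j < len(covariate_names) else f"cov{j}" for j in keep
    )
    return AnalysisResult(
        statistic_name="partial_spearman" if k else "spearman",
        estimate=r,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        n=n,
        adjustment_set=names,
        extra={"df": df},
    )


def adjusted_association(
    data: pd.DataFrame,
    *,
    exposure_col: str = "exposure_words",
    face_col: str = "p_no_disengage_face",
    nonface_col: str = "p_no_disengage_nonface",
    covariate_cols: tuple[str, ...] = (),
    site_col: str = "site",
    zscore_within_site: bool = True,
    ci_reps: int = 2000,
    seed: int | None = 0,
) -> AnalysisResult:
    """Exposure vs. face no-disengagement, adjusted for the non-face score
    (and any further covariates), after per-site z-scoring.

    Rows with a missing value in any used column are dropped listwise;
    the reported n is the analyzed count.  Categorical covariates must
    already be integer-coded (ordinal levels in order, binaries as 0/1) —
    ranking makes the coding scale-free.
    """
    cols = [exposure_col, face_col, nonface_col, *covariate_cols]
    use = [site_col] + cols if zscore_within_site else cols
    d = data[use].dropna()
    x = d[exposure_col].to_numpy(dtype=float)
    yv = d[face_col].to_numpy(dtype=float)
    nf = d[nonface_col].to_numpy(dtype=float)
    if zscore_within_site:
        sites = d[site_col].to_numpy()
        x = zscore_by_site(x, sites)
        yv = zscore_by_site(yv, sites)
        nf = zscore_by_site(nf, sites)
    cov = np.column_stack([nf] + [d[c].to_numpy(dtype=float) for c in covariate_cols])
    return spearman_partial(
        x,
        yv,
        cov,
        ci_reps=ci_reps,
        seed=seed,
        covariate_names=(nonface_col, *covariate_cols),
    )


def parent_face_association(
    exposure,
    parent_face_score,
    unfamiliar_face_score,
    *,
    ci_reps: int = 2000,
    seed: int | None = 0,
) -> AnalysisResult:
    """Exposure vs. parent-face no-disengagement given the unfamiliar-face
    score (the parent-face-preference analysis)."""
    return spearman_partial(
        exposure,
        parent_face_score,
        np.asarray(unfamiliar_face_score, dtype=float)[:, None],
        ci_reps=ci_reps,
        seed=seed,
        covariate_names=("p_no_disengage_unfamiliar_face",),
    )


def twin_subset_sensitivity(
    data: pd.DataFrame,
    twin_pair_ids,
    analysis,
    *,
    max_pairs: int = 20,
) -> SubsetSensitivityResult:
    """Run ``analysis`` on every subset keeping one infant per twin pair.

    ``twin_pair_ids`` aligns with ``data`` rows; empty/NaN marks a
    singleton.  Enumerates all 2^k subsets (k twin pairs), each formed by
    all singletons plus exactly one member of each pair, and collects the
    scalar the callable returns (e.g. a partial r_s).
    """
    ids = pd.Series(np.asarray(twin_pair_ids, dtype=object), index=data.index)
    ids = ids.where(ids.notna(), "").astype(str)
    pair_rows = {}
    for pid, idx in ids[ids != ""].groupby(ids[ids != ""]).groups.items():
        if len(idx) != 2:
            raise ValueError(f"twin pair {pid!r} has {len(idx)} members, expected 2")
        pair_rows[pid] = list(idx)
    k = len(pair_rows)
    if k > max_pairs:
        raise ValueError(f"{k} twin pairs exceeds the enumeration guard ({max_pairs})")
    singles = data.index[ids == ""]
    values = np.empty(2**k)
    pair_list = sorted(pair_rows)
    for i, choice in enumerate(itertools.product((0, 1), repeat=k)):
        chosen = [pair_rows[pid][c] for pid, c in zip(pair_list, choice)]
        subset = data.loc[list(singles) + chosen]
        values[i] = float(analysis(subset))
    return SubsetSensitivityResult(
        n_subsets=2**k,
        r_s_values=values,
        min=float(values.min()),
        max=float(values.max()),
        median=float(np.median(values)),
    )
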