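"""Group-level statistics: pairwise modality/model comparisons, pooled
VO2-vs-%HRR regressions, and line-of-identity regressions.

Comparisons are paired: per-individual differences (absolute, L/min) and
per-individual relative differences (% of the reference value) are tested
against zero with a one-sample t-test (df = n - 1).  Because every value
enters two pairwise comparisons, raw p-values are doubled (Bonferroni)
and capped at 1; significance is declared at p_adj < 0.05.
"""
from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateFitError,
    IncompleteGridError,
    ValidationError,
)
from .types import ComparisonResult, GroupRegression, IntensityEstimate

#: pairwise modality contrasts, (target, reference), reference in denominator
MODE_CONTRASTS = (("walk", "cycle"), ("run", "cycle"), ("run", "walk"))


def bonferroni_double(p_raw: float) -> float:
    """Doubled-p Bonferroni adjustment, capped at 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValidationError(f"p-value must be in [0, 1], got {p_raw}")
    return min(2.0 * p_raw, 1.0)


def significance_stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def _one_sample(values: np.ndarray, alpha: float = 0.05):
    """Mean, SD, t-based CI and two-sided one-sample t-test against zero."""
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    ci = (mean - half, mean + half)
    if sd == 0.0:
        # identical differences: t-test undefined; zero mean is trivially
        # non-significant, non-zero mean trivially significant
        p = 1.0 if mean == 0.0 else 0.0
    else:
        with warnings.catch_warnings():
            # scipy warns about cancellation when diffs are nearly identical
            # (e.g. noise-free simulations); the t-test result is still valid
            warnings.filterwarnings("ignore", message="Precision loss",
                                    category=RuntimeWarning)
            p = float(stats.ttest_1samp(values, 0.0).pvalue)
    return mean, sd, ci, p


def mode_difference(estimates_target, estimates_reference,
                    level_pct: float = float("nan"),
                    contrast: tuple[str, str] = ("target", "reference"),
                    alpha: float = 0.05) -> ComparisonResult:
    """Paired comparison of per-participant VO2 estimates at one level.

    ``estimates_target`` and ``estimates_reference`` map participant id to
    VO2 (dict or pandas Series).  Participants with a zero reference value
    are excluded from the relative statistics with a warning.
    """
    t = pd.Series(dict(estimates_target) if isinstance(estimates_target, Mapping)
                  else estimates_target, dtype=float)
    r = pd.Series(dict(estimates_reference) if isinstance(estimates_reference, Mapping)
                  else estimates_reference, dtype=float)
    if set(t.index) != set(r.index):
        missing = set(t.index) ^ set(r.index)
        raise AlignmentError(
            f"participant sets differ; unmatched ids: {sorted(missing)}"
        )
    if len(t) < 2:
        raise ValidationError("need at least 2 participants for a comparison")
    r = r.reindex(t.index)
    diffs = (t - r).to_numpy()

    mean_abs, sd_abs, ci_abs, p_abs = _one_sample(diffs, alpha)
    p_adj_abs = bonferroni_double(p_abs)

    nonzero = r.to_numpy() != 0.0
    if not np.all(nonzero):
        warnings.warn(
            f"{np.count_nonzero(~nonzero)} participant(s) with zero reference "
            "value excluded from relative differences",
            RuntimeWarning,
            stacklevel=2,
        )
    rel = diffs[nonzero] / r.to_numpy()[nonzero] * 100.0
    if rel.size >= 2:
        mean_rel, sd_rel, ci_rel, p_rel = _one_sample(rel, alpha)
    else:
        mean_rel, sd_rel, ci_rel, p_rel = np.nan, np.nan, (np.nan, np.nan), np.nan
    p_adj_rel = bonferroni_double(p_rel) if np.isfinite(p_rel) else np.nan

    return ComparisonResult(
        contrast=contrast,
        level_pct=level_pct,
        n=len(t),
        mean_abs_diff=mean_abs,
        sd_abs_diff=sd_abs,
        ci95_abs=ci_abs,
        p_raw=p_abs,
        p_adj=p_adj_abs,
        significant=bool(p_adj_abs < 0.05),
        mean_rel_diff=mean_rel,
        sd_rel_diff=sd_rel,
        ci95_rel=ci_rel,
        p_raw_rel=p_rel,
        p_adj_rel=p_adj_rel,
        significant_rel=bool(np.isfinite(p_adj_rel) and p_adj_rel < 0.05),
        n_rel=int(rel.size),
    )


def _ols_with_ci(x: np.ndarray, y: np.ndarray) -> GroupRegression:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = np.asarray(fit.conf_int(alpha=0.05))
    return GroupRegression(
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope=float(fit.params[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        r2=float(fit.rsquared),
        n_points=int(y.size),
    )


def group_level_regression(estimates: pd.DataFrame) -> GroupRegression:
    """Pooled OLS of vo2_est on level_pct over all participant-level points.

    ``estimates`` needs columns participant_id, level_pct, vo2_est and must
    form a complete participant x level grid.  For such balanced designs
    the pooled coefficients equal those of a regression on the per-level
    means.
    """
    required = {"participant_id", "level_pct", "vo2_est"}
    if not required.issubset(estimates.columns):
        raise ValidationError(f"estimates must have columns {sorted(required)}")
    counts = estimates.pivot_table(index="participant_id", columns="level_pct",
                                   values="vo2_est", aggfunc="count")
    missing = [
        (pid, lvl)
        for pid in counts.index
        for lvl in counts.columns
        if pd.isna(counts.loc[pid, lvl])
    ]
    if missing:
        raise IncompleteGridError(f"missing participant x level cells: {missing}")
    return _ols_with_ci(estimates["level_pct"].to_numpy(),
                        estimates["vo2_est"].to_numpy())


def identity_regression(x_estimates, y_estimates) -> GroupRegression:
    """OLS of paired estimates, to be read against the line of identity.

    Intercept near 0, slope near 1 and high r² indicate that the two
    methods (modalities or models) are interchangeable.
    """
    x = np.asarray(x_estimates, dtype=float)
    y = np.asarray(y_estimates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValidationError("need at least 3 paired points")
    return _ols_with_ci(x, y)


def _estimates_frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        return estimates
    rows = [e.__dict__ if not isinstance(e, IntensityEstimate) else {
        "participant_id": e.participant_id, "modality": e.modality,
        "model_kind": e.model_kind, "level_pct": e.level_pct,
        "hr_target": e.hr_target, "vo2_est": e.vo2_est,
        "extrapolated": e.extrapolated, "negative": e.negative,
    } for e in estimates]
    return pd.DataFrame(rows)


def build_report(estimates) -> dict[str, pd.DataFrame]:
    """Machine-readable analogues of the study's summary tables.

    Returns a dict of DataFrames:

    * ``summary`` — per model/modality/level mean ± SD and 95% CI of the
      estimated VO2, plus the (individually derived) HR targets.
    * ``mode_differences`` — three pairwise modality contrasts per model
      and level, absolute and relative, with doubled-p significance.
    * ``group_regressions`` — pooled VO2-on-%HRR line per model/modality.
    * ``identity_modes`` — line-of-identity regressions for the three
      modality pairs within each model.
    * ``identity_models`` — model 2 vs model 1 within each modality.
    """
    df = _estimates_frame(estimates)

    summary_rows = []
    for (kind, modality, level), grp in df.groupby(
            ["model_kind", "modality", "level_pct"]):
        v = grp["vo2_est"].to_numpy()
        mean, sd, ci, _ = _one_sample(v)
        summary_rows.append({
            "model_kind": kind, "modality": modality, "level_pct": level,
            "n": v.size, "vo2_mean": mean, "vo2_sd": sd,
            "vo2_ci_low": ci[0], "vo2_ci_high": ci[1],
            "hr_target_mean": grp["hr_target"].mean(),
            "hr_target_sd": grp["hr_target"].std(ddof=1),
            "n_extrapolated": int(grp["extrapolated"].sum()),
            "n_negative": int(grp["negative"].sum()),
        })
    summary = pd.DataFrame(summary_rows)

    diff_rows = []
    for kind, kind_df in df.groupby("model_kind"):
        wide = kind_df.pivot_table(index="participant_id",
                                   columns=["modality", "level_pct"],
                                   values="vo2_est")
        for target, reference in MODE_CONTRASTS:
            if target not in wide.columns.get_level_values(0):
                continue
            if reference not in wide.columns.get_level_values(0):
                continue
            for level in sorted(kind_df["level_pct"].unique()):
                res = mode_difference(wide[(target, level)],
                                      wide[(reference, level)],
                                      level_pct=level,
                                      contrast=(target, reference))
                diff_rows.append({
                    "model_kind": kind, "target": target,
                    "reference": reference, "level_pct": level, "n": res.n,
                    "mean_abs_diff": res.mean_abs_diff,
                    "sd_abs_diff": res.sd_abs_diff,
                    "ci_abs_low": res.ci95_abs[0],
                    "ci_abs_high": res.ci95_abs[1],
                    "p_raw": res.p_raw, "p_adj": res.p_adj,
                    "stars_abs": significance_stars(res.p_adj),
                    "mean_rel_diff": res.mean_rel_diff,
                    "sd_rel_diff": res.sd_rel_diff,
                    "ci_rel_low": res.ci95_rel[0],
                    "ci_rel_high": res.ci95_rel[1],
                    "p_raw_rel": res.p_raw_rel, "p_adj_rel": res.p_adj_rel,
                    "stars_rel": significance_stars(res.p_adj_rel)
                    if np.isfinite(res.p_adj_rel) else "",
                })
    mode_differences = pd.DataFrame(diff_rows)

    reg_rows = []
    for (kind, modality), grp in df.groupby(["model_kind", "modality"]):
        reg = group_level_regression(grp)
        reg_rows.append({
            "model_kind": kind, "modality": modality,
            "intercept": reg.intercept,
            "intercept_ci_low": reg.intercept_ci[0],
            "intercept_ci_high": reg.intercept_ci[1],
            "slope": reg.slope,
            "slope_ci_low": reg.slope_ci[0],
            "slope_ci_high": reg.slope_ci[1],
            "r2": reg.r2, "n_points": reg.n_points,
        })
    group_regressions = pd.DataFrame(reg_rows)

    def _reg_row(reg: GroupRegression) -> dict:
        return {
            "intercept": reg.intercept,
            "intercept_ci_low": reg.intercept_ci[0],
            "intercept_ci_high": reg.intercept_ci[1],
            "slope": reg.slope,
            "slope_ci_low": reg.slope_ci[0],
            "slope_ci_high": reg.slope_ci[1],
            "r2": reg.r2, "n_points": reg.n_points,
        }

    id_mode_rows = []
    for kind, kind_df in df.groupby("model_kind"):
        wide = kind_df.pivot_table(index=["participant_id", "level_pct"],
                                   columns="modality", values="vo2_est")
        for target, reference in MODE_CONTRASTS:
            if target not in wide.columns or reference not in wide.columns:
                continue
            pair = wide[[reference, target]].dropna()
            reg = identity_regression(pair[reference], pair[target])
            id_mode_rows.append({"model_kind": kind, "y": target,
                                 "x": reference, **_reg_row(reg)})
    identity_modes = pd.DataFrame(id_mode_rows)

    id_model_rows = []
    kinds = sorted(df["model_kind"].unique())
    if set(kinds) >= {1, 2}:
        wide = df.pivot_table(index=["participant_id", "level_pct", "modality"],
                              columns="model_kind", values="vo2_est")
        for modality in sorted(df["modality"].unique()):
            sub = wide.xs(modality, level="modality")
            if 1 not in sub.columns or 2 not in sub.columns:
                continue
            sub = sub[[1, 2]].dropna()
            if len(sub) < 3:
                continue
            reg = identity_regression(sub[1], sub[2])
            id_model_rows.append({"modality": modality, "y": "model2",
                                  "x": "model1", **_reg_row(reg)})
    identity_models = pd.DataFrame(id_model_rows)

    return {
        "summary": summary,
        "mode_differences": mode_differences,
        "group_regressions": group_regressions,
        "identity_modes": identity_modes,
        "identity_models": identity_models,
    }
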