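"""Reliability, validity, and group-difference statistics.

Test-retest reliability of the per-segment gait parameters is assessed
with the two-way random-effects, average-measures, absolute-agreement
intraclass correlation ICC(2,k) — here k = 3 repeated video segments per
subject.  With MS_R, MS_C and MS_E the between-subject, between-segment
and residual mean squares of the two-way ANOVA,

    ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n),

with the p-value from F = MS_R / MS_E and the 95 % confidence interval
by the McGraw-Wong F-based construction.  Values above 0.75 indicate
good consistency (Koo & Li threshold).

Validity against a gold standard is summarized per feature and group by
the Pearson correlation r (r in [0.7, 0.9) high, r >= 0.9 very high)
and the mean difference d between paired measurements.  Group
differences across healthy / early / mid-stage cohorts use the
Kruskal-Wallis rank test with significance marked at 0.05 and 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .pose_model import FEATURE_NAMES, GROUPS


@dataclass
class ICCResult:
    """An intraclass correlation with its uncertainty."""

    icc: float
    ci_low: float
    ci_high: float
    p: float
    n_subjects: int
    k_raters: int
    label: str = ""  # "good" (>0.75 threshold) or "moderate_or_low"

    def __post_init__(self) -> None:
        if not self.label:
            self.label = "good" if self.icc > 0.75 else "moderate_or_low"


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)), n, k)


def icc_2k(data: np.ndarray | pd.DataFrame, alpha: float = 0.05,
           consistency: bool = False) -> ICCResult:
    """ICC for the mean of k repeated measurements per subject.

    ``data`` is a subjects x raters matrix (here raters = segments) with
    no missing cells.  The default is the absolute-agreement ICC(2,k);
    ``consistency=True`` switches to the consistency form ICC(3,k) for
    sensitivity analysis.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ParameterError("data must be a 2-D subjects x raters matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("ICC needs >= 2 subjects and >= 2 raters")
    if not np.isfinite(data).all():
        raise ParameterError("missing or non-finite cells; ICC does not impute")
    msr, msc, mse = _two_way_mean_squares(data)[:3]
    if msr == 0 and mse == 0:
        warnings.warn("zero total variance; ICC undefined", stacklevel=2)
        return ICCResult(np.nan, np.nan, np.nan, np.nan, n, k, label="undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        if consistency:
            icc = (msr - mse) / msr if msr > 0 else np.nan
        else:
            icc = (msr - mse) / (msr + (msc - mse) / n)
        f_obs = msr / mse if mse > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    if consistency:
        f_tab_u = stats.f.ppf(1 - alpha / 2, df1, df2)
        f_tab_l = stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = 1.0 - f_tab_u / f_obs if np.isfinite(f_obs) else 1.0
        hi = 1.0 - 1.0 / (f_obs * f_tab_l) if np.isfinite(f_obs) else 1.0
        return ICCResult(float(icc), float(lo), float(hi), p, n, k)

    # McGraw–Wong interval for ICC(A,1), then Spearman–Brown to k raters
    if mse == 0:
        return ICCResult(float(icc), float(icc), float(icc), p, n, k)
    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    r = max(min(icc_a1, 1 - 1e-12), -1 + 1e-12)
    a = k * r / (n * (1 - r))
    b = 1 + k * r * (n - 1) / (n * (1 - r))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df2))
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    denom_const = k * msc + (k * n - k - n) * mse
    lo1 = n * (msr - f_u * mse) / (f_u * denom_const + n * msr)
    hi1 = n * (f_l * msr - mse) / (denom_const + n * f_l * msr)
    sb = lambda x: x * k / (1 + (k - 1) * x)  # noqa: E731 — Spearman–Brown
    return ICCResult(float(icc), float(sb(lo1)), float(sb(hi1)), p, n, k)


_R_BANDS = ((0.9, "very_high"), (0.7, "high"))


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Product-moment correlation with the qualitative band it falls in."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("pearson_r needs paired samples of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return np.nan, "undefined"
    r = float(stats.pearsonr(x, y).statistic)
    for cut, name in _R_BANDS:
        if r >= cut:
            return r, name
    return r, "lower"


def kruskal_wallis(*groups: np.ndarray) -> dict[str, float | bool]:
    """Rank-based H test for differences among >= 2 groups.

    Returns the tie-corrected H statistic, the chi-square p-value, and
    significance flags at the 0.05 (*) and 0.01 (**) levels.
    """
    if len(groups) < 2:
        raise ParameterError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ParameterError("all groups must be non-empty")
    if sum(len(g) for g in arrays) < 5:
        raise InsufficientDataError(
            "chi-square approximation needs a total of >= 5 observations")
    if np.ptp(np.concatenate(arrays)) == 0:  # all values identical
        return {"H": 0.0, "p": 1.0, "significant_05": False, "significant_01": False}
    H, p = stats.kruskal(*arrays)
    return {"H": float(H), "p": float(p),
            "significant_05": bool(p < 0.05), "significant_01": bool(p < 0.01)}


def group_difference_report(features: pd.DataFrame,
                            feature_names: tuple[str, ...] = FEATURE_NAMES,
                            ) -> pd.DataFrame:
    """Kruskal-Wallis comparison of every feature across the groups present."""
    present = [g for g in GROUPS if (features["group"] == g).any()]
    if len(present) < 2:
        raise ParameterError("group comparison needs at least two groups")
    rows = []
    for name in feature_names:
        groups = [features.loc[features["group"] == g, name].dropna().to_numpy()
                  for g in present]
        res = kruskal_wallis(*groups)
        rows.append({"feature": name, **res})
    return pd.DataFrame(rows)


def validity_report(video_features: pd.DataFrame, gold_features: pd.DataFrame,
                    feature_names: tuple[str, ...] = FEATURE_NAMES,
                    ) -> pd.DataFrame:
    """Agreement of video-derived features with a gold standard.

    Rows are matched on (subject_id, segment_id); the output has one row
    per feature and pooled group (healthy vs pd), with means, SDs,
    Pearson r and mean absolute / signed differences.
    """
    keys = ["subject_id", "segment_id"]
    merged = video_features.merge(gold_features, on=keys,
                                  suffixes=("_video", "_gold"))
    if len(merged) != len(video_features) or len(merged) != len(gold_features):
        unmatched = (set(map(tuple, video_features[keys].to_numpy()))
                     ^ set(map(tuple, gold_features[keys].to_numpy())))
        raise ParameterError(f"unmatched (subject, segment) keys: "
                             f"{sorted(unmatched)[:5]} ...")
    group_col = ("group_video" if "group_video" in merged.columns else "group")
    pooled = merged[group_col].map(
        lambda g: "healthy" if g == "healthy" else "pd")
    rows = []
    for group in ("pd", "healthy"):
        sub = merged[pooled == group]
        if not len(sub):
            continue
        for name in feature_names:
            gold = sub[f"{name}_gold"].to_numpy()
            video = sub[f"{name}_video"].to_numpy()
            r, band = pearson_r(gold, video) if len(sub) >= 3 else (np.nan, "n/a")
            rows.append({
                "feature": name, "group": group,
                "gold_mean": gold.mean(), "gold_sd": gold.std(ddof=1),
                "video_mean": video.mean(), "video_sd": video.std(ddof=1),
                "r": r, "r_band": band,
                "d": np.abs(video - gold).mean(),
                "d_signed": (video - gold).mean(),
            })
    return pd.DataFrame(rows)


def reliability_report(features: pd.DataFrame,
                       feature_names: tuple[str, ...] = FEATURE_NAMES,
                       segments_per_subject: int = 3,
                       consistency: bool = False) -> pd.DataFrame:
    """Per-group, per-feature ICC(2,k) across repeated segments.

    Subjects contributing a number of segments different from
    ``segments_per_subject`` are excluded with a warning (the inclusion
    rule is at least three valid segments per participant).
    """
    counts = features.groupby("subject_id").size()
    bad = counts[counts != segments_per_subject].index
    if len(bad):
        warnings.warn(f"excluding {len(bad)} subject(s) without exactly "
                      f"{segments_per_subject} segments", stacklevel=2)
        features = features[~features["subject_id"].isin(bad)]
    rows = []
    for group in GROUPS:
        sub = features[features["group"] == group]
        if not len(sub):
            continue
        for name in feature_names:
            mat = sub.pivot_table(index="subject_id", columns="segment_id",
                                  values=name)
            res = icc_2k(mat.to_numpy(), consistency=consistency)
            rows.append({"group": group, "feature": name, "icc": res.icc,
                         "p": res.p, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "n_subjects": res.n_subjects,
                         "k_segments": res.k_raters, "label": res.label})
    return pd.DataFrame(rows)
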