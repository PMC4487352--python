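"""Session aggregation, age binning and the group-comparison battery.

Analysis proceeds session-first: per-call features are averaged within each
recording session, and group-level ("grand") means are means of session
means, never call-weighted pools. Postnatal days map onto four age bins
(1 / 1.5 / 2 / 3 months) with deliberate gaps between the bin edges.

The statistical battery is intentionally plain: an EDF normality check
(Anderson-Darling with Stephens' small-sample correction, alpha = 10 %),
an F test for variance equality, and a two-tailed t test with no
multiple-testing correction, at alpha = 5 %. When the F test rejects
variance equality the unequal-variance (Welch) t form is used; normality
failures are flagged in the output rather than switching tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

ALPHA_NORMALITY = 0.10
ALPHA = 0.05

#: postnatal-day ranges of the four age bins (months -> inclusive day range)
AGE_BINS = {1.0: (30, 35), 1.5: (36, 42), 2.0: (44, 58), 3.0: (64, 103)}

#: feature columns aggregated per session
SUMMARY_FEATURES = ("duration_s", "level_db", "f0_mean_hz", "f0_max_hz",
                    "f0_sd_hz", "t_f0max_s", "hr_mean", "hr_sd", "hr_max",
                    "t_hrmax_s", "hr_at_f0max")
#: features defined only for voiced calls
VOICED_ONLY_FEATURES = ("f0_mean_hz", "f0_max_hz", "f0_sd_hz", "t_f0max_s",
                        "hr_mean", "hr_sd", "hr_max", "t_hrmax_s",
                        "hr_at_f0max")


@dataclass
class SessionSummary:
    session_id: str
    animal_id: str
    group: str
    postnatal_day: int
    age_bin: Optional[float]
    n_calls: int
    pct_voiced: float
    duration_s: float = float("nan")
    level_db: float = float("nan")
    f0_mean_hz: float = float("nan")
    f0_max_hz: float = float("nan")
    f0_sd_hz: float = float("nan")
    t_f0max_s: float = float("nan")
    hr_mean: float = float("nan")
    hr_sd: float = float("nan")
    hr_max: float = float("nan")
    t_hrmax_s: float = float("nan")
    hr_at_f0max: float = float("nan")


@dataclass
class ComparisonResult:
    feature: str
    group_a: str
    group_b: str
    test: str  # "t_two_tailed" or "f_var"
    statistic: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    normality_pass_a: Optional[bool] = None
    normality_pass_b: Optional[bool] = None
    equal_var_assumed: Optional[bool] = None


def age_bin(postnatal_day: int) -> Optional[float]:
    """Map a postnatal day onto the 1/1.5/2/3-month bins; days falling in
    the gaps (43, 59-63, <30, >103) return None."""
    if postnatal_day < 1:
        raise ValueError("postnatal day must be >= 1")
    for months, (lo, hi) in AGE_BINS.items():
        if lo <= postnatal_day <= hi:
            return months
    return None


def summarize_session(features: pd.DataFrame | Sequence, metadata: dict
                      ) -> SessionSummary:
    """Per-session means of call features.

    Duration and level average over all calls; F0 and harmonic-ratio
    statistics average over voiced calls only. ``pct_voiced`` counts the
    fraction of all detected calls classified voiced.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame([asdict(f) if not isinstance(f, dict) else f
                                 for f in features])
    if len(features) == 0:
        raise ValueError("cannot summarize a session with no calls")
    voiced = features[features["call_class"] == "voiced"]
    out = SessionSummary(
        session_id=str(metadata.get("session_id", "")),
        animal_id=str(metadata.get("animal_id", "")),
        group=str(metadata.get("group", "")),
        postnatal_day=int(metadata.get("postnatal_day", 0)),
        age_bin=age_bin(int(metadata.get("postnatal_day", 0)))
        if metadata.get("postnatal_day") else None,
        n_calls=len(features),
        pct_voiced=100.0 * len(voiced) / len(features),
    )
    for col in SUMMARY_FEATURES:
        src = voiced if col in VOICED_ONLY_FEATURES else features
        if col in src.columns and len(src):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                setattr(out, col, float(np.nanmean(src[col].to_numpy())))
    return out


def summaries_frame(summaries: Sequence[SessionSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def grand_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-group grand means: the mean of session means, all ages pooled."""
    cols = ["pct_voiced", "n_calls", *SUMMARY_FEATURES]
    cols = [c for c in cols if c in summaries.columns]
    return summaries.groupby("group")[cols].mean()


def normality_test(sample: np.ndarray, alpha: float = ALPHA_NORMALITY
                   ) -> tuple[float, bool]:
    """EDF normality test (Anderson-Darling, Stephens' case with estimated
    mean and variance) against the alpha = 10 % critical value.

    Returns ``(statistic, passed)``. A zero-variance sample fails outright.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 5:
        raise ValueError("normality test needs n >= 5")
    if np.std(x) == 0:
        return float("inf"), False
    res = sst.anderson(x, dist="norm", method="interpolate")
    return float(res.statistic), bool(res.pvalue > alpha)


def compare_groups(a: np.ndarray, b: np.ndarray, feature: str = "",
                   group_a: str = "a", group_b: str = "b",
                   alpha_var: float = ALPHA
                   ) -> tuple[ComparisonResult, ComparisonResult]:
    """Variance-equality F test plus two-tailed t test for two samples.

    F = larger sample variance / smaller, with a two-sided p; the t test
    uses the pooled form when the F test does not reject at 5 %, otherwise
    the Welch form. No multiple-testing correction is applied.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        f_stat, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        f_stat, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p_f = min(1.0, 2.0 * float(sst.f.sf(f_stat, dfn, dfd)))
    equal_var = p_f >= alpha_var
    t_res = sst.ttest_ind(a, b, equal_var=equal_var)
    norm_a = normality_test(a)[1] if a.size >= 5 else None
    norm_b = normality_test(b)[1] if b.size >= 5 else None
    common = dict(feature=feature, group_a=group_a, group_b=group_b,
                  n_a=int(a.size), n_b=int(b.size),
                  normality_pass_a=norm_a, normality_pass_b=norm_b)
    var_result = ComparisonResult(test="f_var", statistic=float(f_stat),
                                  p_value=p_f, df=float(dfn), **common)
    mean_result = ComparisonResult(test="t_two_tailed",
                                   statistic=float(t_res.statistic),
                                   p_value=float(t_res.pvalue),
                                   df=float(t_res.df),
                                   equal_var_assumed=equal_var, **common)
    return var_result, mean_result


def developmental_table(summaries: pd.DataFrame,
                        features: Sequence[str] = SUMMARY_FEATURES,
                        min_n: int = 2) -> pd.DataFrame:
    """Long-format table of the full comparison battery.

    For every feature: within-group comparisons across all age-bin pairs,
    and within-age comparisons across all group pairs. Cells with fewer
    than ``min_n`` sessions are skipped.
    """
    df = summaries.dropna(subset=["age_bin"])
    if df["age_bin"].nunique() < 2:
        raise ValueError("need at least two populated age bins")
    rows = []

    def emit(feature, ga, gb, age_a, age_b, xa, xb):
        if len(xa) < min_n or len(xb) < min_n:
            return
        xa = xa[np.isfinite(xa)]
        xb = xb[np.isfinite(xb)]
        if len(xa) < min_n or len(xb) < min_n or \
                (np.var(xa) == 0 and np.var(xb) == 0):
            return
        var_r, mean_r = compare_groups(xa, xb, feature, str(ga), str(gb))
        for r in (var_r, mean_r):
            rows.append({"feature": feature, "group_a": ga, "group_b": gb,
                         "age_a": age_a, "age_b": age_b, "test": r.test,
                         "statistic": r.statistic, "p": r.p_value,
                         "n_a": r.n_a, "n_b": r.n_b,
                         "mean_a": float(np.mean(xa)),
                         "mean_b": float(np.mean(xb))})

    groups = sorted(df["group"].unique())
    ages = sorted(df["age_bin"].unique())
    for feature in features:
        if feature not in df.columns:
            continue
        # within group, across age
        for g in groups:
            sub = df[df["group"] == g]
            for i, age_a in enumerate(ages):
                for age_b in ages[i + 1:]:
                    emit(feature, g, g, age_a, age_b,
                         sub[sub["age_bin"] == age_a][feature].to_numpy(),
                         sub[sub["age_bin"] == age_b][feature].to_numpy())
        # within age, across group
        for age in ages:
            sub = df[df["age_bin"] == age]
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    emit(feature, ga, gb, age, age,
                         sub[sub["group"] == ga][feature].to_numpy(),
                         sub[sub["group"] == gb][feature].to_numpy())
    return pd.DataFrame(rows, columns=["feature", "group_a", "group_b",
                                       "age_a", "age_b", "test", "statistic",
                                       "p", "n_a", "n_b", "mean_a", "mean_b"])
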