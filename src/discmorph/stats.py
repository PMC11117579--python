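"""Reliability and method-comparison statistics over NP-to-CSA ratio tables.

Implements the analysis layer used to judge the measurement protocol:

* Pearson correlation with the conventional interpretation bands
  (Excellent > 0.810; Good 0.61-0.809; Moderate 0.410-0.609; Fair
  0.210-0.409; Poor < 0.209).  The printed band edges leave tiny gaps
  (e.g. 0.809-0.810); a value falling in a gap is assigned to the lower
  band so the classification is total and deterministic.
* Paired-sample t test and per-pair absolute error (|x - y| / x, in percent
  of the first measurement — deliberately asymmetric).
* Intraclass correlation ICC(2,1): two-way random effects, absolute
  agreement, single rater.
* Split-plot factorial ANOVA: gender as the between-subject factor, spinal
  level as the within-subject factor, subject nested in gender as the
  between-stratum error term.
* Tukey HSD all-pairs comparisons via the studentized range distribution
  (Tukey-Kramer standard errors for unequal group sizes).

A small simulator of ratio tables with configurable gender/level effects
supports power and type-I-error studies of the ANOVA layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PCC_BANDS",
    "classify_pcc",
    "pearson_with_band",
    "PairedTResult",
    "paired_t",
    "absolute_error",
    "icc_absolute_agreement",
    "split_plot_anova",
    "tukey_hsd",
    "ReliabilityReport",
    "repeatability_report",
    "simulate_ratio_table",
]

# (lower bound, band name); values above the top bound are Excellent,
# gap values fall into the band below the gap.
PCC_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.810, "Excellent"),  # strictly greater than
    (0.610, "Good"),
    (0.410, "Moderate"),
    (0.210, "Fair"),
)


def classify_pcc(pcc: float) -> str:
    """Interpretation band for a Pearson correlation coefficient."""
    if not -1.0 <= pcc <= 1.0 + 1e-12:
        raise ValueError("PCC must lie in [-1, 1]")
    if pcc > PCC_BANDS[0][0]:
        return PCC_BANDS[0][1]
    for lower, name in PCC_BANDS[1:]:
        if pcc >= lower:
            return name
    return "Poor"


def pearson_with_band(x: Sequence[float], y: Sequence[float]) -> Tuple[float, str]:
    """Pearson product-moment correlation plus its interpretation band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    pcc = float(sps.pearsonr(x, y).statistic)
    return pcc, classify_pcc(pcc)


@dataclass(frozen=True)
class PairedTResult:
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    degenerate: bool = False


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired-sample t test on (x - y).

    Identical pairs give t = 0, p = 1.  Constant nonzero differences have
    zero variance; the result is flagged degenerate (t undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired series with n >= 3")
    d = x - y
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if md == 0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0)
        return PairedTResult(np.inf, n - 1, 0.0, md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), n - 1, p, md)


def absolute_error(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Per-pair absolute error 100·|x−y|/x and its summary statistics.

    The error is expressed relative to the *first* measurement, so it is
    asymmetric in (x, y) by definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if np.any(x == 0):
        raise ValueError("first measurement contains zeros; error undefined")
    e = 100.0 * np.abs(x - y) / np.abs(x)
    summary = {
        "mean": float(e.mean()),
        "sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
        "min": float(e.min()),
        "max": float(e.max()),
    }
    return e, summary


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an n-subjects x k-raters table with no missing cells.
    Computed from the classical mean squares of the two-way ANOVA without
    replication:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 3 or R.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 3 subjects, k >= 2 raters")
    if np.any(~np.isfinite(R)):
        raise ValueError("ratings table has missing cells")
    n, k = R.shape
    grand = R.mean()
    ssr = k * float(((R.mean(axis=1) - grand) ** 2).sum())
    ssc = n * float(((R.mean(axis=0) - grand) ** 2).sum())
    sst = float(((R - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: no variance anywhere in the table")
    return float((msr - mse) / denom)


def _sum_contrast(series: pd.Series) -> np.ndarray:
    """Sum-to-zero (effect) coding: one column per non-reference level."""
    cats = sorted(series.unique())
    ref = cats[-1]
    cols = []
    for cat in cats[:-1]:
        col = np.where(series == cat, 1.0, 0.0) - np.where(series == ref, 1.0, 0.0)
        cols.append(col)
    return np.stack(cols, axis=1)


def _validate_split_plot(
    df: pd.DataFrame, dv: str, between: str, within: str, subject: str
) -> None:
    levels = sorted(df[within].unique())
    missing = []
    for sid, sub in df.groupby(subject):
        have = sorted(sub[within].tolist())
        if have != levels:
            missing.append((sid, sorted(set(levels) - set(have))))
        if sub[between].nunique() != 1:
            raise ValueError(f"subject {sid!r} appears under multiple {between} groups")
    if missing:
        raise ValueError(f"incomplete within-subject cells: {missing[:5]}")
    cell_counts = df.groupby([between, within], observed=True)[dv].count()
    small = cell_counts[cell_counts < 2]
    if len(small):
        raise ValueError(f"cells with fewer than 2 observations: {list(small.index)}")


def split_plot_anova(
    df: pd.DataFrame,
    dv: str = "ratio_percent",
    between: str = "gender",
    within: str = "disc_level",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Split-plot (mixed between/within) factorial ANOVA.

    The between-subject factor (gender) is tested against subjects nested in
    gender; the within-subject factor (spinal level) and the interaction are
    tested against the subject-by-level residual.  Within-stratum sums of
    squares are type III (sum-to-zero coding), so mildly unbalanced group
    sizes are handled; every subject must be measured at every level.

    Returns a table with one row per effect: sum_sq, df, F, p_value plus the
    two error strata.
    """
    work = df[[dv, between, within, subject]].copy()
    _validate_split_plot(work, dv, between, within, subject)
    k = work[within].nunique()

    # between stratum: one observation per subject (its mean over levels),
    # scaled by k so sums of squares are on the per-observation scale
    subj = (
        work.groupby([subject, between], observed=True)[dv].mean().reset_index()
    )
    grand = subj[dv].mean()
    g_means = subj.groupby(between, observed=True)[dv].agg(["mean", "count"])
    ss_g = k * float((g_means["count"] * (g_means["mean"] - grand) ** 2).sum())
    df_g = len(g_means) - 1
    ss_e1 = k * float(
        ((subj[dv] - subj[between].map(g_means["mean"])) ** 2).sum()
    )
    df_e1 = len(subj) - len(g_means)
    f_g = (ss_g / df_g) / (ss_e1 / df_e1)
    p_g = float(sps.f.sf(f_g, df_g, df_e1))

    # within stratum: subject dummies absorb all between-subject variation;
    # level and interaction get partial (type III) sums of squares via
    # model comparison on sum-to-zero contrast columns
    y = work[dv].to_numpy(dtype=float)
    subj_dummies = pd.get_dummies(work[subject], drop_first=True).to_numpy(float)
    lev_contrast = _sum_contrast(work[within])
    bet_contrast = _sum_contrast(work[between])
    inter = np.concatenate(
        [bet_contrast[:, [i]] * lev_contrast for i in range(bet_contrast.shape[1])],
        axis=1,
    )
    ones = np.ones((len(y), 1))

    def rss(*blocks: np.ndarray) -> Tuple[float, int]:
        X = np.concatenate(blocks, axis=1)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum()), int(rank)

    rss_full, rank_full = rss(ones, subj_dummies, lev_contrast, inter)
    df_e2 = len(y) - rank_full
    rss_no_w, _ = rss(ones, subj_dummies, inter)
    rss_no_i, _ = rss(ones, subj_dummies, lev_contrast)
    ss_w = rss_no_w - rss_full
    df_w = k - 1
    ss_i = rss_no_i - rss_full
    df_i = (len(g_means) - 1) * (k - 1)
    ss_e2 = rss_full
    ms_e2 = ss_e2 / df_e2
    f_w = (ss_w / df_w) / ms_e2
    f_i = (ss_i / df_i) / ms_e2

    rows = [
        (between, ss_g, df_g, f_g, p_g),
        (f"subject({between})", ss_e1, df_e1, np.nan, np.nan),
        (within, ss_w, df_w, f_w, float(sps.f.sf(f_w, df_w, df_e2))),
        (f"{between}:{within}", ss_i, df_i, f_i, float(sps.f.sf(f_i, df_i, df_e2))),
        ("residual", ss_e2, df_e2, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["effect", "sum_sq", "df", "F", "p_value"]).set_index(
        "effect"
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's honest significant difference over all group pairs.

    Pooled within-group variance, Tukey-Kramer standard errors for unequal
    sample sizes, adjusted p from the studentized range distribution.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    k = len(names)
    n_total = sum(v.size for v in samples.values())
    df_err = n_total - k
    pooled_var = (
        sum((v.size - 1) * v.var(ddof=1) for v in samples.values()) / df_err
    )
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        v1, v2 = samples[g1], samples[g2]
        diff = float(v1.mean() - v2.mean())
        se = np.sqrt(pooled_var / 2.0 * (1.0 / v1.size + 1.0 / v2.size))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append((g1, g2, diff, float(se), float(q), p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["group1", "group2", "mean_diff", "se", "q_stat", "p_adj", "reject"],
    )


@dataclass(frozen=True)
class ReliabilityReport:
    """Repeatability summary for two paired measurement series."""

    pcc: float
    pcc_band: str
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    abs_error_mean: float
    abs_error_sd: float
    abs_error_min: float
    abs_error_max: float
    icc: float


def repeatability_report(x: Sequence[float], y: Sequence[float]) -> ReliabilityReport:
    """Full repeatability analysis of two measurement rounds."""
    pcc, band = pearson_with_band(x, y)
    t = paired_t(x, y)
    _, err = absolute_error(x, y)
    icc = icc_absolute_agreement(np.column_stack([x, y]))
    return ReliabilityReport(
        pcc=pcc,
        pcc_band=band,
        t_stat=t.t_stat,
        df=t.df,
        p_value=t.p_value,
        mean_diff=t.mean_diff,
        abs_error_mean=err["mean"],
        abs_error_sd=err["sd"],
        abs_error_min=err["min"],
        abs_error_max=err["max"],
        icc=icc,
    )


def simulate_ratio_table(
    n_female: int = 10,
    n_male: int = 10,
    levels: Sequence[str] = ("L1/L2", "L2/L3", "L3/L4", "L4/L5"),
    baseline: float = 38.0,
    gender_effect: float = 0.0,
    level_effects: Optional[Sequence[float]] = None,
    interaction: Optional[np.ndarray] = None,
    subject_sd: float = 6.0,
    resid_sd: float = 2.0,
    seed: int = 0,
    method: str = "fcm",
) -> pd.DataFrame:
    """Simulate a ratio table for the split-plot design.

    Each subject (nested in gender) contributes one measurement per spinal
    level.  The generating model is

        y = baseline ± gender_effect/2 + level_effect + interaction
            + subject_effect + noise,

    with subject effects N(0, subject_sd²) and residual noise
    N(0, resid_sd²).  Defaults mirror a healthy-cohort NP-to-CSA study:
    baseline 38%, between-subject sd 6 points, measurement noise 2 points,
    four lumbar levels.
    """
    rng = np.random.default_rng(seed)
    levels = list(levels)
    nl = len(levels)
    le = np.zeros(nl) if level_effects is None else np.asarray(level_effects, float)
    if le.size != nl:
        raise ValueError("level_effects length must match levels")
    inter = np.zeros((2, nl)) if interaction is None else np.asarray(interaction, float)
    rows = []
    sid = 0
    for gi, (gender, n_g) in enumerate((("F", n_female), ("M", n_male))):
        g_shift = (-0.5 if gender == "F" else 0.5) * gender_effect
        for _ in range(n_g):
            sid += 1
            subj_eff = rng.normal(0.0, subject_sd)
            for li, level in enumerate(levels):
                y = (
                    baseline
                    + g_shift
                    + le[li]
                    + inter[gi, li]
                    + subj_eff
                    + rng.normal(0.0, resid_sd)
                )
                rows.append((f"S{sid:03d}", gender, level, method, y))
    return pd.DataFrame(
        rows, columns=["subject_id", "gender", "disc_level", "method", "ratio_percent"]
    )
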