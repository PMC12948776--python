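"""Repeated-measures agreement statistics for device-versus-criterion HR.

Implements the agreement toolkit for validation studies where each subject
contributes many paired observations:

* Bland-Altman limits of agreement for repeated measures with a varying true
  value: the SD of a single difference combines within- and between-subject
  variance components estimated from a one-way ANOVA of the differences on
  subject, with the unequal-replicates correction
  ``n0 = (sum(m) - sum(m^2)/sum(m)) / (k - 1)``.
* Agreement grading of the limits (excellent <= 5 bpm, good <= 10 bpm,
  unacceptable beyond), read as the larger absolute limit.
* Proportional bias as the Pearson trend of the difference against the
  criterion value (modified Bland-Altman plot convention).
* The repeated-measures correlation coefficient r_rm from the common-slope
  ANCOVA with a subject factor.
* Mean absolute error by protocol intensity, one-way repeated-measures
  ANOVA with Greenhouse-Geisser correction, Bonferroni-adjusted pairwise
  paired t tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: LoA grade thresholds in bpm: (excellent, good)
GRADE_THRESHOLDS = (5.0, 10.0)


# ---------------------------------------------------------------------------
# Bland-Altman for repeated measures


@dataclass
class BlandAltmanResult:
    """Bias and repeated-measures limits of agreement, bpm."""

    bias: float
    sd_total: float
    loa_lower: float
    loa_upper: float
    sigma2_between: float
    ms_within: float
    n_obs: int
    n_subjects: int


def limits_of_agreement(bias: float, sd: float, z: float = 1.96) -> tuple[float, float]:
    """95% limits of agreement ``bias -/+ z * sd``."""
    return bias - z * sd, bias + z * sd


def bland_altman_rm(differences, subjects, z: float = 1.96) -> BlandAltmanResult:
    """Repeated-measures Bland-Altman analysis of paired differences.

    ``differences`` are device-minus-criterion values; ``subjects`` the
    parallel subject labels.  The variance of a single difference is
    ``sigma2_between + MS_within`` where the between-subject component comes
    from the one-way ANOVA of differences on subject (negative estimates
    truncated to zero).  With exactly one difference per subject the method
    degenerates gracefully to the classic Bland-Altman sample SD.
    """
    d = np.asarray(differences, dtype=float)
    codes, uniques = pd.factorize(np.asarray(subjects))
    if d.size == 0:
        raise ValueError("no differences")
    if d.size != codes.size:
        raise ValueError("differences and subjects differ in length")
    k = len(uniques)
    if k < 2:
        raise ValueError(
            "between-subject variance unidentifiable with a single subject"
        )
    n = d.size
    m = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=d, minlength=k)
    means = sums / m
    grand = d.mean()
    ssb = float(np.sum(m * (means - grand) ** 2))
    ssw = float(np.sum((d - means[codes]) ** 2))
    msb = ssb / (k - 1)
    if np.all(m == 1):
        # classic single-observation Bland-Altman
        sigma2_b = 0.0
        msw = float(np.var(d, ddof=1))
        sd_total = np.sqrt(msw)
    else:
        msw = ssw / (n - k)
        n0 = (m.sum() - np.sum(m**2) / m.sum()) / (k - 1)
        sigma2_b = max(0.0, (msb - msw) / n0)
        sd_total = float(np.sqrt(sigma2_b + msw))
    lo, hi = limits_of_agreement(grand, sd_total, z)
    return BlandAltmanResult(
        bias=float(grand),
        sd_total=float(sd_total),
        loa_lower=lo,
        loa_upper=hi,
        sigma2_between=float(sigma2_b),
        ms_within=float(msw),
        n_obs=int(n),
        n_subjects=int(k),
    )


def classify_agreement(
    loa_lower: float,
    loa_upper: float,
    thresholds: tuple[float, float] = GRADE_THRESHOLDS,
) -> str:
    """Grade agreement from the limits: the larger absolute limit decides.

    ``<= thresholds[0]`` bpm is excellent, ``<= thresholds[1]`` good,
    anything wider unacceptable.
    """
    if not (np.isfinite(loa_lower) and np.isfinite(loa_upper)):
        raise ValueError("non-finite limits of agreement")
    if loa_lower > loa_upper:
        raise ValueError("lower limit exceeds upper limit")
    excellent, good = thresholds
    width = max(abs(loa_lower), abs(loa_upper))
    if width <= excellent:
        return "excellent"
    if width <= good:
        return "good"
    return "unacceptable"


def proportional_bias(criterion_hr, differences) -> tuple[float, float]:
    """Pearson trend of the difference against criterion HR.

    Returns ``(r, p)``; with constant differences (or constant criterion)
    the trend is undefined and ``(nan, nan)`` is returned.
    """
    x = np.asarray(criterion_hr, dtype=float)
    y = np.asarray(differences, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired epochs for the trend")
    if np.std(y) == 0 or np.std(x) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Repeated-measures correlation (common-slope ANCOVA)


@dataclass
class RmcorrResult:
    """Repeated-measures correlation coefficient and its F test."""

    r_rm: float
    df: int
    p: float


def rmcorr(x, y, subjects) -> RmcorrResult:
    """Within-subject correlation via the subject-factor ANCOVA.

    Both variables are centred within subject; the coefficient is the signed
    square root of ``SS_measure / (SS_measure + SS_error)`` where
    ``SS_measure = (sum x~ y~)^2 / sum x~^2`` on the centred values, with
    ``df = N - k - 1`` and the p value from ``F(1, df)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(subjects))
    k = len(uniques)
    n = x.size
    counts = np.bincount(codes, minlength=k)
    if k < 2 or np.sum(counts >= 2) < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    xc = x - (np.bincount(codes, weights=x) / counts)[codes]
    yc = y - (np.bincount(codes, weights=y) / counts)[codes]
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("no within-subject variance in x")
    sxy = float(np.sum(xc * yc))
    syy = float(np.sum(yc**2))
    ss_measure = sxy**2 / sxx
    ss_error = syy - ss_measure
    df = n - k - 1
    if ss_measure + ss_error == 0:
        raise ValueError("no within-subject variance in y")
    r = np.sign(sxy) * np.sqrt(ss_measure / (ss_measure + ss_error))
    if ss_error <= 0:  # perfect fit
        return RmcorrResult(float(r), df, 0.0)
    f = ss_measure / (ss_error / df)
    p = float(stats.f.sf(f, 1, df))
    return RmcorrResult(float(r), df, p)


# ---------------------------------------------------------------------------
# MAE by intensity and the intensity comparisons


def mae_by_intensity(matched: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the absolute epoch error per device and intensity."""
    if "intensity" not in matched:
        raise ValueError("matched epochs carry no intensity labels")
    out = (
        matched.groupby(["device_id", "intensity"], sort=False)["abs_error"]
        .agg(mae="mean", sd=lambda v: v.std(ddof=1), n_epochs="size")
        .reset_index()
    )
    return out


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""

    f: float
    df1: float
    df2: float
    p: float
    epsilon_gg: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    n_subjects: int


def _gg_epsilon(table: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    c = table.shape[1]
    s = np.cov(table, rowvar=False, ddof=1)
    center = np.eye(c) - np.ones((c, c)) / c
    sc = center @ s @ center
    tr = np.trace(sc)
    denom = (c - 1) * np.trace(sc @ sc)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / (c - 1), 1.0))


def rm_anova(table) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subject x condition table.

    Reports the uncorrected F test and the Greenhouse-Geisser corrected
    degrees of freedom and p value (epsilon estimated from the covariance
    matrix; both are always reported, the corrected p being the conservative
    choice whenever epsilon < 1).
    """
    a = np.asarray(table, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a subject x condition table")
    n, c = a.shape
    if c < 2:
        raise ValueError("need >= 2 conditions")
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if np.isnan(a).any():
        raise ValueError("incomplete table; apply listwise deletion first")
    grand = a.mean()
    ss_cond = n * np.sum((a.mean(axis=0) - grand) ** 2)
    ss_subj = c * np.sum((a.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((a - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = c - 1
    df2 = (c - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else float("inf")
    else:
        f = ms_cond / ms_err
    eps = _gg_epsilon(a)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    p_gg = float(stats.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else 0.0
    return RmAnovaResult(
        f=float(f),
        df1=float(df1),
        df2=float(df2),
        p=p,
        epsilon_gg=eps,
        df1_gg=eps * df1,
        df2_gg=eps * df2,
        p_gg=p_gg,
        n_subjects=n,
    )


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t test; returns ``(t, df, p)``.

    Degenerate difference variance is handled explicitly: zero variance with
    zero mean difference gives ``t = 0, p = 1``; zero variance with a
    nonzero mean difference is reported as ``t = +/-inf, p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired t needs equal lengths >= 2")
    d = x - y
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def bonferroni_pairwise(table, labels=None) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise paired t tests between conditions.

    ``table`` is a complete subject x condition array; every pair of columns
    is compared with a paired t test and the raw p value multiplied by the
    number of pairs (capped at 1).
    """
    a = np.asarray(table, dtype=float)
    c = a.shape[1]
    if labels is None:
        labels = list(range(c))
    pairs = list(itertools.combinations(range(c), 2))
    rows = []
    for i, j in pairs:
        t, df, p = paired_t(a[:, i], a[:, j])
        rows.append(
            {
                "a": labels[i],
                "b": labels[j],
                "t": t,
                "df": df,
                "p_raw": p,
                "p_adj": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
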