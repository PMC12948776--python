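"""Random-intercept linear mixed model of heart-rate measurement error.

The per-epoch absolute error MAE_HR is modelled as

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma2_b),  e_ij ~ N(0, sigma2_e)

with a random intercept per subject.  Estimation is maximum likelihood (not
REML), so that likelihood-ratio tests between models differing in fixed
effects are valid; the marginal likelihood is maximized by profiling beta and
sigma2_e analytically and searching the one-dimensional variance ratio
lambda = sigma2_b / sigma2_e on the log scale.

Model building follows forward entry: starting from the intercept-only
model, each candidate predictor (skin pigmentation as ITA degrees first,
then criterion HR) is added and kept iff the likelihood-ratio test against
the current model is significant.  Derived summaries: ICC from the null
model, marginal R^2 (share of total variance explained by the non-intercept
fixed effects), squared semi-partial correlations as marginal-R^2
differences against leave-one-out refits, and variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

INTERCEPT = "intercept"

_LOG_RATIO_BOUNDS = (-30.0, 15.0)
_LOGLIK_TOL = 1e-10


@dataclass
class MixedModelFit:
    """Fitted random-intercept model (maximum likelihood)."""

    beta: pd.Series
    beta_se: pd.Series
    sigma2_b: float
    sigma2_e: float
    loglik: float
    n_obs: int
    n_subjects: int
    fe_names: list[str]
    converged: bool = True
    _X: np.ndarray = field(repr=False, default=None)

    @property
    def icc(self) -> float:
        """Share of total variance at the subject level."""
        return self.sigma2_b / (self.sigma2_b + self.sigma2_e)

    @property
    def marginal_r2(self) -> float:
        return marginal_r2(self)


def _design(X, n_obs: int) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effect design with a leading intercept column."""
    if X is None:
        return np.ones((n_obs, 1)), [INTERCEPT]
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    full = np.column_stack([np.ones(mat.shape[0]), mat])
    return full, [INTERCEPT] + names


def fit_random_intercept(y, X, subject_ids, method: str = "ML") -> MixedModelFit:
    """Fit the Gaussian random-intercept model by profiled ML.

    Parameters
    ----------
    y : array-like
        Response (per-epoch absolute error, bpm).
    X : DataFrame, array or None
        Non-intercept fixed-effect columns; an intercept is always added.
        ``None`` fits the intercept-only model.
    subject_ids : array-like
        Grouping labels; one random intercept per distinct value.
    method : str
        Only ``"ML"`` is supported (likelihood-ratio tests on fixed effects
        require it).
    """
    if method != "ML":
        raise ValueError("only ML estimation is supported")
    y = np.asarray(y, dtype=float)
    n = y.size
    Xf, names = _design(X, n)
    p = Xf.shape[1]
    if n <= p + 2:
        raise ValueError("too few observations for the requested fixed effects")
    if np.linalg.matrix_rank(Xf) < p:
        raise ValueError("fixed-effect design is rank deficient")
    codes, uniques = pd.factorize(np.asarray(subject_ids))
    k = len(uniques)
    if k < 2:
        raise ValueError("need >= 2 subjects")
    m = np.bincount(codes, minlength=k).astype(float)

    if np.all(m == 1.0):
        warnings.warn(
            "one observation per subject: sigma2_b unidentifiable, fitting OLS",
            stacklevel=2,
        )
        return _finalize(y, Xf, names, codes, m, ratio=0.0, converged=True)

    # Sufficient statistics that do not depend on the variance ratio.
    XtX = Xf.T @ Xf
    Xty = Xf.T @ y
    yty = float(y @ y)
    SX = np.zeros((k, p))
    for j in range(p):
        SX[:, j] = np.bincount(codes, weights=Xf[:, j], minlength=k)
    Sy = np.bincount(codes, weights=y, minlength=k)

    def profile_negloglik(log_ratio: float) -> float:
        lam = np.exp(log_ratio)
        w = lam / (1.0 + lam * m)
        A = XtX - SX.T @ (w[:, None] * SX)
        b = Xty - SX.T @ (w * Sy)
        beta = np.linalg.solve(A, b)
        yVy = yty - float(w @ Sy**2)
        rVr = yVy - float(beta @ b)
        rVr = max(rVr, 1e-300)
        sigma2_e = rVr / n
        logdet = float(np.sum(np.log1p(lam * m)))
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2_e) + logdet + n)
        return -ll

    res = optimize.minimize_scalar(
        profile_negloglik,
        bounds=_LOG_RATIO_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    ratio = float(np.exp(res.x))
    # A boundary solution at the lower bound is an effectively zero
    # between-subject component; report it as exactly zero (OLS limit).
    if -profile_negloglik(_LOG_RATIO_BOUNDS[0]) >= -res.fun - _LOGLIK_TOL:
        ratio = 0.0
    return _finalize(y, Xf, names, codes, m, ratio, converged=bool(res.success))


def _finalize(y, Xf, names, codes, m, ratio, converged) -> MixedModelFit:
    n = y.size
    k = m.size
    lam = ratio
    w = lam / (1.0 + lam * m)
    p = Xf.shape[1]
    SX = np.zeros((k, p))
    for j in range(p):
        SX[:, j] = np.bincount(codes, weights=Xf[:, j], minlength=k)
    Sy = np.bincount(codes, weights=y, minlength=k)
    A = Xf.T @ Xf - SX.T @ (w[:, None] * SX)
    b = Xf.T @ y - SX.T @ (w * Sy)
    beta = np.linalg.solve(A, b)
    yVy = float(y @ y) - float(w @ Sy**2)
    rVr = max(yVy - float(beta @ b), 1e-300)
    sigma2_e = rVr / n
    sigma2_b = lam * sigma2_e
    logdet = float(np.sum(np.log1p(lam * m)))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_e) + logdet + n)
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    return MixedModelFit(
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(se, index=names),
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        loglik=float(loglik),
        n_obs=int(n),
        n_subjects=int(k),
        fe_names=list(names),
        converged=converged,
        _X=Xf,
    )


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested ML fits."""

    chi2: float
    df: int
    p: float


def lrt(fit_reduced: MixedModelFit, fit_full: MixedModelFit) -> LRTResult:
    """Likelihood-ratio test for nested fixed effects on identical data."""
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits use different data")
    if not set(fit_reduced.fe_names) <= set(fit_full.fe_names):
        raise ValueError("models are not nested")
    df = len(fit_full.fe_names) - len(fit_reduced.fe_names)
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if chi2 < -1e-6:
        raise ValueError(f"negative LR statistic ({chi2:.3g}); fits inconsistent")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(float(chi2), int(df), p)


def forward_entry(
    y,
    candidates: pd.DataFrame,
    subject_ids,
    alpha: float = 0.05,
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Forward-entry selection of fixed effects by likelihood-ratio test.

    Candidates are tried in column order (pigmentation first, then criterion
    HR in the reference analysis); each is kept iff the LRT against the
    current model has ``p < alpha``.  Returns the final fit and a per-step
    trace (predictor, chi2, df, p, kept).
    """
    kept: list[str] = []
    current = fit_random_intercept(y, None, subject_ids)
    rows = []
    for name in candidates.columns:
        trial = fit_random_intercept(y, candidates[kept + [name]], subject_ids)
        res = lrt(current, trial)
        keep = res.p < alpha
        rows.append(
            {
                "step": len(rows) + 1,
                "predictor": name,
                "chi2": res.chi2,
                "df": res.df,
                "p": res.p,
                "kept": keep,
                "loglik": trial.loglik,
            }
        )
        if keep:
            kept.append(name)
            current = trial
    return current, pd.DataFrame(rows)


def icc_from_null(y, subject_ids) -> float:
    """ICC from the intercept-only random-intercept fit."""
    return fit_random_intercept(y, None, subject_ids).icc


def marginal_r2(fit: MixedModelFit) -> float:
    """Share of total variance explained by the non-intercept fixed effects.

    ``Var(X beta)`` is taken over the observed design, excluding the
    intercept column; the denominator adds both variance components.
    """
    slope_cols = [i for i, nm in enumerate(fit.fe_names) if nm != INTERCEPT]
    if not slope_cols:
        return 0.0
    fixed = fit._X[:, slope_cols] @ fit.beta.to_numpy()[slope_cols]
    var_f = float(np.var(fixed))
    return var_f / (var_f + fit.sigma2_b + fit.sigma2_e)


def semipartial_sr2(
    y, candidates: pd.DataFrame, predictors: list[str], subject_ids
) -> dict[str, float]:
    """Squared semi-partial correlation per predictor.

    Defined as the drop in marginal R^2 when the predictor is removed from
    the full model (refit on identical data), floored at zero.  This is a
    mixed-model analogue of the classical sr^2, labelled as such in outputs.
    """
    for p in predictors:
        if p not in candidates.columns:
            raise ValueError(f"predictor {p!r} not among candidates")
    full = fit_random_intercept(y, candidates[predictors], subject_ids)
    r2_full = marginal_r2(full)
    out = {}
    for p in predictors:
        rest = [q for q in predictors if q != p]
        reduced = fit_random_intercept(
            y, candidates[rest] if rest else None, subject_ids
        )
        out[p] = max(0.0, r2_full - marginal_r2(reduced))
    return out


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor column.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the remaining
    columns (with intercept).  A single predictor has VIF 1 by definition;
    perfect collinearity is reported as ``inf`` with a warning.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return pd.Series(1.0, index=cols)
    out = {}
    for j, name in enumerate(cols):
        yj = X[name].to_numpy(dtype=float)
        others = X[[c for c in cols if c != name]].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"perfect collinearity involving {name!r}; VIF infinite",
                stacklevel=2,
            )
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)
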