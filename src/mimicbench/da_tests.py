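"""The differential abundance test battery.

Every test consumes a features x samples matrix (already transformed as
appropriate) plus binary group labels and returns a :class:`DAResult` with
one p-value (or, for the ANCOM W-test, a score that is explicitly *not* a
p-value) and one statistic per feature.  Features for which a test cannot
produce a p-value (degenerate variance, all ties) carry p = 1, matching the
downstream missing-p convention.

Confounder-aware variants: a stratified (van Elteren style) Wilcoxon test,
a fixed-effect linear model (label + covariate) and a random-intercept
linear mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "DAResult",
    "wilcoxon_test",
    "t_test",
    "ks_test",
    "linear_model_test",
    "moderated_t_test",
    "ancom_w_test",
    "DEFAULT_TRANSFORM",
]

#: default input transform per test (overridable by the caller)
DEFAULT_TRANSFORM = {
    "wilcoxon": "TSS",
    "wilcoxon-blocked": "TSS",
    "ks": "TSS",
    "ttest": "TSS.log",
    "lm": "TSS.log",
    "lm-fixed": "TSS.log",
    "lmem": "TSS.log",
    "modt": "TSS.log",
    "ancomw": None,  # raw counts
}


@dataclass
class DAResult:
    method: str
    p: np.ndarray
    statistic: np.ndarray
    transform_used: Optional[str] = None
    covariate_used: bool = False
    is_pvalue: bool = True
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)


def _split(matrix: np.ndarray, labels: np.ndarray):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = np.asarray(labels)
    x = matrix[:, labels == 1]
    y = matrix[:, labels == 0]
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return matrix, x, y


# ---------------------------------------------------------------------------
# Wilcoxon / Mann-Whitney, naive and stratified
# ---------------------------------------------------------------------------


def wilcoxon_test(
    matrix: np.ndarray, labels: np.ndarray, block: Optional[np.ndarray] = None
) -> DAResult:
    """Two-sided rank-sum test per feature, optionally stratified by block.

    Naive: mid-ranks for ties; exact enumeration of the rank-sum
    distribution when both groups together hold <= 25 untied observations,
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  With ``block`` given, a van Elteren style
    stratified test combines within-stratum centered rank sums (weights
    1/(N_s + 1)); strata where one group is empty are dropped with a
    warning, and a single effective stratum reduces to the naive test.
    """
    matrix, x, y = _split(matrix, labels)
    if block is not None:
        return _stratified_wilcoxon(matrix, labels, np.asarray(block))
    n = x.shape[1] + y.shape[1]
    if n <= 25:
        p = np.empty(matrix.shape[0])
        u = np.empty(matrix.shape[0])
        for i in range(matrix.shape[0]):
            has_ties = np.unique(np.concatenate([x[i], y[i]])).size < n
            method = "asymptotic" if has_ties else "exact"
            res = stats.mannwhitneyu(x[i], y[i], alternative="two-sided", method=method)
            u[i], p[i] = res.statistic, res.pvalue
    else:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=-1)
        u, p = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    return DAResult("wilcoxon", p, u, covariate_used=block is not None)


def _stratified_wilcoxon(matrix: np.ndarray, labels: np.ndarray, block: np.ndarray) -> DAResult:
    strata = []
    for s in np.unique(block):
        cols = np.flatnonzero(block == s)
        if (labels[cols] == 1).sum() == 0 or (labels[cols] == 0).sum() == 0:
            warnings.warn(f"stratum {s!r} lacks one group; dropped")
            continue
        strata.append(cols)
    if not strata:
        raise ValueError("no stratum contains both groups")
    if len(strata) == 1:
        res = wilcoxon_test(matrix[:, strata[0]], labels[strata[0]])
        res.covariate_used = True
        res.method = "wilcoxon-blocked"
        return res

    num = np.zeros(matrix.shape[0])
    var = np.zeros(matrix.shape[0])
    for cols in strata:
        sub = matrix[:, cols]
        lab = labels[cols]
        ns = cols.size
        n1 = int((lab == 1).sum())
        n2 = ns - n1
        ranks = stats.rankdata(sub, axis=1)
        w = ranks[:, lab == 1].sum(axis=1)
        e = n1 * (ns + 1) / 2.0
        # tie correction per feature within the stratum
        tie_term = np.zeros(matrix.shape[0])
        for i in range(matrix.shape[0]):
            _, counts = np.unique(sub[i], return_counts=True)
            tie_term[i] = ((counts**3 - counts).sum()) / (ns * (ns - 1))
        v = n1 * n2 / 12.0 * ((ns + 1) - tie_term)
        weight = 1.0 / (ns + 1)
        num += weight * (w - e)
        var += weight**2 * v
    with np.errstate(invalid="ignore", divide="ignore"):
        z = num / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(p), 1.0, p)
    return DAResult("wilcoxon-blocked", p, z, covariate_used=True)


# ---------------------------------------------------------------------------
# t-test / KS
# ---------------------------------------------------------------------------


def t_test(matrix: np.ndarray, labels: np.ndarray) -> DAResult:
    """Welch's two-sided t-test per feature (unequal variances)."""
    matrix, x, y = _split(matrix, labels)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(x, y, axis=-1, equal_var=False)
    t = np.atleast_1d(np.asarray(res.statistic, dtype=float))
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p = np.where(degenerate | np.isnan(p), 1.0, p)
    t = np.where(degenerate | np.isnan(t), 0.0, t)
    return DAResult("ttest", p, t, flags={"degenerate_variance": degenerate})


def ks_test(matrix: np.ndarray, labels: np.ndarray) -> DAResult:
    """Two-sample two-sided Kolmogorov-Smirnov test per feature."""
    matrix, x, y = _split(matrix, labels)
    m = matrix.shape[0]
    d = np.empty(m)
    p = np.empty(m)
    for i in range(m):
        res = stats.ks_2samp(x[i], y[i], alternative="two-sided", method="asymp")
        d[i], p[i] = res.statistic, min(res.pvalue, 1.0)
    return DAResult("ks", p, d)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


def _ols_batch(matrix: np.ndarray, X: np.ndarray, coef_idx: int):
    """Shared-design OLS across features; returns (beta, se, df, singular)."""
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        return None
    xtx_inv = np.linalg.inv(xtx)
    H = xtx_inv @ X.T
    beta = H @ matrix.T  # (k, features)
    resid = matrix.T - X @ beta
    df = n - k
    s2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(s2 * xtx_inv[coef_idx, coef_idx])
    return beta[coef_idx], se, df, s2


def linear_model_test(
    matrix: np.ndarray,
    labels: np.ndarray,
    covariate: Optional[np.ndarray] = None,
    covariate_role: str = "fixed",
) -> DAResult:
    """Per-feature linear model of (transformed) abundance on the label.

    Naive (no covariate): OLS ``y ~ label``; the label's F-test p-value
    (identical to the pooled two-sample t-test, F = t^2).  Fixed covariate:
    OLS ``y ~ label + covariate``, partial t-test for the label.  Random
    covariate: per-feature random-intercept mixed model
    ``y ~ label + (1|covariate)`` (Wald p for the label); non-convergence
    falls back to the fixed-effect p with a flag, and a single-level
    covariate reduces to the naive model.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = np.asarray(labels, dtype=float)
    n = labels.size

    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if np.unique(covariate).size < 2:
            covariate = None  # degenerate grouping: naive model

    if covariate is None:
        X = np.column_stack([np.ones(n), labels])
        out = _ols_batch(matrix, X, 1)
        if out is None:
            return DAResult("lm", np.ones(matrix.shape[0]), np.zeros(matrix.shape[0]),
                            flags={"singular": True})
        beta, se, df, _ = out
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        f = t**2
        p = stats.f.sf(f, 1, df)
        p = np.where(np.isnan(p), 1.0, p)
        return DAResult("lm", p, np.where(np.isnan(f), 0.0, f))

    if covariate_role == "fixed":
        X = np.column_stack([np.ones(n), labels, covariate])
        out = _ols_batch(matrix, X, 1)
        if out is None:
            return DAResult("lm-fixed", np.ones(matrix.shape[0]), np.zeros(matrix.shape[0]),
                            covariate_used=True, flags={"singular": True})
        beta, se, df, _ = out
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isnan(p), 1.0, p)
        return DAResult("lm-fixed", p, np.where(np.isnan(t), 0.0, t), covariate_used=True)

    if covariate_role != "random":
        raise ValueError("covariate_role must be 'fixed' or 'random'")
    return _mixed_model_test(matrix, labels, covariate)


def _mixed_model_test(matrix: np.ndarray, labels: np.ndarray, covariate: np.ndarray) -> DAResult:
    import statsmodels.api as sm

    fallback = linear_model_test(matrix, labels, covariate, covariate_role="fixed")
    m = matrix.shape[0]
    p = np.ones(m)
    t = np.zeros(m)
    fell_back = np.zeros(m, dtype=bool)
    X = np.column_stack([np.ones(labels.size), labels])
    groups = np.asarray(covariate)
    for i in range(m):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(matrix[i], X, groups=groups).fit(reml=True, method="lbfgs")
            pv = float(fit.pvalues[1])
            if not np.isfinite(pv):
                raise ValueError("non-finite p")
            p[i] = pv
            t[i] = float(fit.tvalues[1])
        except Exception:
            p[i] = fallback.p[i]
            t[i] = fallback.statistic[i]
            fell_back[i] = True
    return DAResult("lmem", p, t, covariate_used=True, flags={"fell_back": fell_back})


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float):
    """Moment-match log residual variances to an F prior; (d0, s0^2)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    target = evar - special.polygamma(1, df / 2.0)
    if target <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(target)
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def moderated_t_test(matrix: np.ndarray, labels: np.ndarray) -> DAResult:
    """Per-feature moderated t-statistic with empirical-Bayes shrinkage.

    Residual variances from the per-feature linear model ``y ~ label`` are
    shrunk toward a common prior, s~^2 = (d0*s0^2 + d*s^2)/(d0 + d), with
    (d0, s0^2) estimated by moment matching of log residual variances
    (trigamma inversion).  The moderated t has d0 + d degrees of freedom;
    d0 = inf pools all variances, d0 = 0 recovers the ordinary t-test.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if (labels == 1).sum() < 3 or (labels == 0).sum() < 3:
        raise ValueError("need >= 3 samples per group")
    n = labels.size
    X = np.column_stack([np.ones(n), labels])
    beta, se_unit, df, s2 = _ols_batch(matrix, X, 1)
    # se_unit = s * sqrt(v); recover sqrt(v) to re-scale with shrunk variance
    with np.errstate(invalid="ignore", divide="ignore"):
        sqrt_v = np.where(s2 > 0, se_unit / np.sqrt(s2), np.nan)
    sqrt_v = np.where(np.isfinite(sqrt_v), sqrt_v, np.nanmedian(sqrt_v))
    d0, s0 = _squeeze_var(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / (np.sqrt(s2_tilde) * sqrt_v)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    return DAResult("modt", p, np.where(np.isnan(t), 0.0, t),
                    flags={"d0": d0, "s0_sq": s0})


# ---------------------------------------------------------------------------
# ANCOM W-score
# ---------------------------------------------------------------------------


def ancom_w_test(
    matrix: np.ndarray,
    labels: np.ndarray,
    alpha_inner: float = 0.05,
    pseudocount: float = 1.0,
) -> DAResult:
    """ANCOM W statistics converted to a monotone (0, 1] score.

    For each feature i, W_i counts the features j != i whose pairwise
    log-ratio log((x_i+pc)/(x_j+pc)) differs between groups at
    ``alpha_inner`` (rank-sum test).  W at or above the recommended decision
    threshold 0.7*(m-1) maps linearly into (0, 0.05) (a "discovery"); lower
    W maps linearly into [0.05, 1].  The mapping is strictly decreasing in
    W.  Scores are NOT p-values and must bypass multiple-testing adjustment
    (``is_pvalue=False``).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    m = matrix.shape[0]
    if m < 3:
        raise ValueError("ANCOM needs at least 3 features")
    labels = np.asarray(labels)
    logx = np.log(matrix + pseudocount)
    x_mask = labels == 1
    y_mask = labels == 0
    w = np.zeros(m, dtype=int)
    for i in range(m):
        lr = logx[i][None, :] - logx  # (m, n) log-ratios vs every feature
        lr = np.delete(lr, i, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                lr[:, x_mask], lr[:, y_mask], alternative="two-sided",
                method="asymptotic", axis=-1,
            )
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        w[i] = int((pvals < alpha_inner).sum())

    tau = 0.7 * (m - 1)
    score = np.empty(m)
    hi = w >= tau
    # high W -> (0, 0.05), low W -> (0.05, 1]; both branches strictly decreasing
    score[hi] = 0.05 * (1.0 - (w[hi] - tau + 0.5) / (m - tau))
    score[~hi] = 1.0 - 0.95 * w[~hi] / tau
    return DAResult("ancomw", score, w.astype(float), is_pvalue=False)
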