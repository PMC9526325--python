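"""Regression engines and the CC-GWAS baseline test.

The fits are deliberately lean (plain numpy least squares / IRLS with Wald
statistics) because the power and type-I experiments run hundreds of
thousands of small regressions; they are cross-checked against statsmodels
in the test suite.

Cohort-level tests pass family identifiers as ``clusters``: siblings share
parents' disease statuses, half their genotypes and a polygenic component,
so i.i.d. standard errors are anti-conservative (the LT-FH liability scores
of two siblings are especially strongly correlated). With clusters the fits
use generalized estimating equations with an exchangeable within-family
working correlation and model-based covariance — for the offspring
regressions the family members are genuinely exchangeable (full siblings),
so this matches a family random-intercept mixed model while staying stable
for rare variants, where per-cluster empirical (sandwich) variances are
driven by a handful of carrier families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = ["AssociationResult", "linear_fit", "logistic_fit", "ccgwas_test"]

#: IRLS stops when the log-likelihood improves by less than this.
LOGISTIC_TOL = 1e-8
LOGISTIC_MAX_ITER = 50
#: |beta| beyond this on a standardized design is treated as separation.
_SEPARATION_BOUND = 30.0


@dataclass
class AssociationResult:
    """Wald test for a single predictor of interest.

    ``statistic = beta / sqrt(variance)``; the p-value is two-sided normal.
    ``converged`` is False for rank-deficient designs, detected separation,
    or IRLS running out of iterations; such results count as non-rejections
    in the power tallies.
    """

    beta: float
    variance: float
    statistic: float
    pvalue: float
    n: int
    converged: bool = True

    @classmethod
    def failed(cls, n: int) -> "AssociationResult":
        return cls(np.nan, np.nan, np.nan, 1.0, n, converged=False)


def _wald(beta: float, variance: float, n: int) -> AssociationResult:
    if not np.isfinite(variance) or variance <= 0:
        return AssociationResult.failed(n)
    z = beta / np.sqrt(variance)
    p = 2.0 * norm.sf(abs(z))
    return AssociationResult(float(beta), float(variance), float(z), max(float(p), 5e-324), n)


def _design(X: np.ndarray, add_intercept: bool) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([X, np.ones(X.shape[0])])
    return X


class _ClusterIndex:
    """Precomputed grouping of rows into clusters (families)."""

    def __init__(self, clusters):
        clusters = np.asarray(clusters)
        self.order = np.argsort(clusters, kind="stable")
        sorted_cl = clusters[self.order]
        self.starts = np.flatnonzero(np.r_[True, sorted_cl[1:] != sorted_cl[:-1]])
        self.sizes = np.diff(np.r_[self.starts, sorted_cl.size])
        self.n_pairs = float(np.sum(self.sizes * (self.sizes - 1) // 2))

    def sums(self, arr):
        """Per-cluster column sums of ``arr`` (rows reordered internally)."""
        return np.add.reduceat(arr[self.order], self.starts, axis=0)


def _estimate_exchangeable_rho(resid, ci: _ClusterIndex, n_params: int, max_rho: float):
    """Moment estimate of the within-cluster correlation of residuals."""
    n = resid.shape[0]
    scale = float(resid @ resid) / max(n - n_params, 1)
    if scale <= 0 or ci.n_pairs == 0:
        return 0.0, scale
    t = ci.sums(resid[:, None])[:, 0]
    sq = ci.sums((resid**2)[:, None])[:, 0]
    cross = float(np.sum(t**2 - sq)) / 2.0
    rho = cross / (ci.n_pairs * scale)
    # lower bound keeps the working covariance PD; the upper bound is the
    # caller's structural constraint (e.g. the additive-kinship bound 0.5
    # for full siblings), defaulting to an unstructured 0.99
    return float(np.clip(rho, 0.0, max_rho)), scale


def _gls_normal_matrices(X, resid, ci: _ClusterIndex, rho):
    """X' V^-1 X and X' V^-1 r for block-exchangeable V (unit scale).

    V_f^-1 = a I + b_f J with a = 1/(1-rho), b_f depending on cluster size.
    """
    a = 1.0 / (1.0 - rho)
    b = -rho / ((1.0 - rho) * (1.0 + (ci.sizes - 1.0) * rho))
    S = ci.sums(X)
    t = ci.sums(resid[:, None])[:, 0]
    xtvx = a * (X.T @ X) + (S * b[:, None]).T @ S
    xtvr = a * (X.T @ resid) + S.T @ (b * t)
    return xtvx, xtvr


def linear_fit(y, X, add_intercept: bool = True, clusters=None, max_rho: float = 0.99) -> AssociationResult:
    """Linear regression of ``y`` on ``X``; reports the first column of ``X``.

    Without ``clusters`` this is OLS with the classical Wald statistic. With
    ``clusters`` (family ids) the fit is iterated feasible GLS under an
    exchangeable within-cluster residual correlation — equivalent to a
    family random-intercept mixed model — with model-based covariance.
    The p-value is two-sided normal.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return AssociationResult.failed(n)
    if np.linalg.cond(xtx) > 1e12:
        return AssociationResult.failed(n)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    if sigma2 == 0.0:
        # exact fit: zero sampling variance, p-value -> 0 for nonzero beta
        stat = np.inf if beta[0] != 0 else 0.0
        return AssociationResult(float(beta[0]), 0.0, stat, 5e-324 if beta[0] else 1.0, n)
    if clusters is None:
        return _wald(beta[0], sigma2 * xtx_inv[0, 0], n)

    ci = _ClusterIndex(clusters)
    for _ in range(20):
        rho, sigma2 = _estimate_exchangeable_rho(resid, ci, p, max_rho)
        xtvx, xtvy = _gls_normal_matrices(X, y, ci, rho)
        try:
            new_beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return AssociationResult.failed(n)
        if np.max(np.abs(new_beta - beta)) < 1e-10 * (1.0 + np.max(np.abs(beta))):
            beta = new_beta
            break
        beta = new_beta
        resid = y - X @ beta
    try:
        cov = sigma2 * np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return AssociationResult.failed(n)
    return _wald(beta[0], cov[0, 0], n)


def logistic_fit(y, X, add_intercept: bool = True, clusters=None, max_rho: float = 0.99) -> AssociationResult:
    """Logistic regression of a binary response; reports the first column.

    Without ``clusters`` this is the MLE via iteratively reweighted least
    squares, converging when the log-likelihood changes by less than 1e-8
    (up to 50 iterations), with the observed-information Wald variance.
    With ``clusters`` the fit continues as a GEE with exchangeable
    within-cluster working correlation (moment-estimated from Pearson
    residuals each iteration) and model-based covariance. Perfect separation
    (diverging coefficients on the standardized design) and non-convergence
    are flagged rather than raised.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response must contain both classes")
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")

    # standardize non-constant columns for numerical stability; the Wald
    # z and p-value are invariant, beta/variance are mapped back at the end
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    p = Xs.shape[1]
    ci = _ClusterIndex(clusters) if clusters is not None else None

    beta = np.zeros(p)
    ll_old = -np.inf
    rho = 0.0
    phi = 1.0
    _last_step = np.inf
    converged = False
    for _ in range(LOGISTIC_MAX_ITER):
        eta = Xs @ beta
        mu = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        # the independence log-likelihood is only a monitor for the GEE path,
        # which additionally requires the scoring step itself to vanish
        if np.abs(ll - ll_old) < LOGISTIC_TOL and (ci is None or _last_step < 1e-8):
            converged = True
            break
        ll_old = ll
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        w = mu * (1.0 - mu)
        sw = np.sqrt(w)
        Xw = Xs * sw[:, None]  # A^{1/2} X
        pearson = (y - mu) / sw
        if ci is not None:
            rho, phi = _estimate_exchangeable_rho(pearson, ci, p, max_rho)
            xtvx, xtvr = _gls_normal_matrices(Xw, pearson, ci, rho)
        else:
            xtvx = Xw.T @ Xw
            xtvr = Xw.T @ pearson
        try:
            step = np.linalg.solve(xtvx, xtvr)
        except np.linalg.LinAlgError:
            return AssociationResult.failed(n)
        beta = beta + step
        _last_step = float(np.max(np.abs(step)))
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _SEPARATION_BOUND:
            return AssociationResult.failed(n)  # separation / divergence

    if not converged:
        return AssociationResult.failed(n)
    mu = expit(Xs @ beta)
    if np.all(np.abs(y - mu) < 1e-8):
        return AssociationResult.failed(n)  # complete separation
    w = mu * (1.0 - mu)
    sw = np.sqrt(w)
    Xw = Xs * sw[:, None]
    if ci is not None:
        xtvx, _ = _gls_normal_matrices(Xw, np.zeros(n), ci, rho)
        xtvx = xtvx / phi  # model-based GEE covariance with estimated scale
    else:
        xtvx = Xw.T @ Xw
    try:
        cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return AssociationResult.failed(n)
    return _wald(beta[0] / scale[0], cov[0, 0] / scale[0] ** 2, n)


def offspring_design(cohort, genotypes, variant: int, adjust_covariates: bool = True):
    """Genotype + (age, sex) design over the proband (offspring) rows."""
    rows = np.flatnonzero(cohort.is_offspring)
    g = genotypes.codes[rows, variant].astype(np.float64)
    if adjust_covariates:
        X = np.column_stack([g, cohort.age[rows], cohort.sex[rows].astype(np.float64)])
    else:
        X = g[:, None]
    return rows, X


def ccgwas_test(
    cohort, genotypes, z, variant: int, adjust_covariates: bool = True
) -> AssociationResult:
    """Standard case-control GWAS: logistic regression of offspring status on
    offspring genotype, adjusting for age and sex, with family-cluster-robust
    standard errors (siblings are correlated in both status and genotype).

    Only the offspring (probands; n = 1000 in the default 400-family design)
    enter the regression, as if parental genotypes were unavailable.
    """
    rows, X = offspring_design(cohort, genotypes, variant, adjust_covariates)
    # full siblings: additive kinship bounds the exchangeable correlation at 0.5
    return logistic_fit(np.asarray(z)[rows], X, clusters=cohort.family[rows], max_rho=0.5)
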