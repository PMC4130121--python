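"""Robust correlation machinery: Box-Cox shaping, multivariate-t EM covariance,
Fisher-z confidence intervals and the Steiger-Williams test for dependent
correlations.

The correlation estimator fits a multivariate t distribution with fixed
degrees of freedom by EM: observations far from the current location in
Mahalanobis distance receive weights (df + p) / (df + d_i^2) < 1, which
bounds the influence of outliers.  As df -> infinity the weights tend to 1
and the estimate converges to the ordinary sample mean/covariance, hence
the Pearson correlation.

The Steiger comparison uses the Williams-modified t statistic for two
correlations sharing one variable, estimated on the same n subjects
(df = n - 3), the variant recommended for the single-shared-variable case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, DomainError, InsufficientDataError


@dataclass(frozen=True)
class CorrelationResult:
    """A (possibly transformed, robust) correlation with its 95% CI."""

    r: float
    ci_low: float
    ci_high: float
    n: int
    lambda_x: Optional[float] = None
    lambda_y: Optional[float] = None
    method: str = "t_em"


@dataclass(frozen=True)
class SteigerResult:
    t_stat: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Box-Cox

def boxcox_transform(x, lam: float):
    """(x^lam - 1)/lam, natural log when |lam| < 1e-8.  Requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("Box-Cox requires strictly positive values")
    if abs(lam) < 1e-8:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def boxcox_loglik(x, lam: float) -> float:
    """Profile log-likelihood of lambda under the normal model (Jacobian included)."""
    x = np.asarray(x, dtype=float)
    y = boxcox_transform(x, lam)
    n = x.size
    var = y.var(ddof=0)
    if var <= 0:
        return -np.inf
    return float(-n / 2.0 * np.log(var) + (lam - 1.0) * np.log(x).sum())


def boxcox_lambda(x, grid: Optional[np.ndarray] = None) -> float:
    """Grid argmax of the Box-Cox profile log-likelihood over [-3, 3], step 0.01."""
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("Box-Cox lambda selection needs n >= 5")
    if np.any(x <= 0):
        raise DomainError("Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        raise DomainError("Box-Cox lambda undefined for a constant vector")
    if grid is None:
        grid = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 2)
    ll = np.array([boxcox_loglik(x, lam) for lam in grid])
    return float(grid[int(np.argmax(ll))])


# ---------------------------------------------------------------------------
# Multivariate-t EM covariance

def t_cov_em(
    X,
    df: float = 4.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM estimate of location and scatter under a multivariate t with fixed df.

    Returns ``(location, scatter, correlation)``.  Each E-step computes
    weights w_i = (df + p) / (df + d_i^2) with d_i^2 the Mahalanobis
    distance under the current estimates; the M-step is the weighted mean
    and weighted (by w_i, normalised by n) scatter.  Convergence when the
    largest absolute change of any parameter is below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DomainError("X must be a 2-D array")
    n, p = X.shape
    if p < 2 or n <= p:
        raise DomainError(f"need n > p >= 2, got n={n}, p={p}")
    if np.any(~np.isfinite(X)):
        raise DomainError("X contains missing or non-finite values")
    if np.any(np.ptp(X, axis=0) == 0):
        raise DomainError("X contains a constant column")

    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=0)
    for _ in range(max_iter):
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("scatter matrix became singular during EM") from exc
        diff = X - mu
        sol = np.linalg.solve(chol, diff.T)
        d2 = np.einsum("ij,ij->j", sol, sol)
        w = (df + p) / (df + d2)
        mu_new = (w[:, None] * X).sum(axis=0) / w.sum()
        diff = X - mu_new
        sigma_new = (w[:, None] * diff).T @ diff / n
        delta = max(
            np.max(np.abs(mu_new - mu)),
            np.max(np.abs(sigma_new - sigma)),
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"t-EM did not converge in {max_iter} iterations")
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return mu, sigma, corr


# ---------------------------------------------------------------------------
# Correlation confidence interval and Steiger comparison

def corr_ci(r: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Fisher z-transform confidence interval: tanh(atanh(r) +/- z/sqrt(n-3))."""
    if not -1.0 < r < 1.0:
        raise DomainError(f"r must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise InsufficientDataError("Fisher-z interval needs n > 3")
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def correlation_with_ci(
    r: float,
    n: int,
    level: float = 0.95,
    lambda_x: Optional[float] = None,
    lambda_y: Optional[float] = None,
    method: str = "t_em",
) -> CorrelationResult:
    lo, hi = corr_ci(r, n, level)
    return CorrelationResult(r, lo, hi, n, lambda_x, lambda_y, method)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Williams-Steiger t for two dependent correlations sharing variable j.

    Tests H0: rho_jk = rho_jh given the correlation r_kh between the two
    non-shared variables, all estimated on the same n subjects.
    df = n - 3; two-sided p from the t distribution.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise DomainError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise InsufficientDataError("Steiger test needs n > 3")
    det = 1.0 - r_jk**2 - r_jh**2 - r_kh**2 + 2.0 * r_jk * r_jh * r_kh
    if det < -1e-10:
        raise DomainError("inconsistent correlation triple (matrix not PSD)")
    det = max(det, 0.0)
    rbar = (r_jk + r_jh) / 2.0
    denom = 2.0 * (n - 1) / (n - 3) * det + rbar**2 * (1.0 - r_kh) ** 3
    if denom <= 0:
        raise DomainError("degenerate correlation configuration in Steiger test")
    t = (r_jk - r_jh) * math.sqrt((n - 1) * (1.0 + r_kh) / denom)
    df = n - 3
    p = 2.0 * stats.t.sf(abs(t), df)
    return SteigerResult(t_stat=t, df=df, p_value=min(p, 1.0))


def compare_correlations_abs(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> SteigerResult:
    """Steiger comparison of |r_jk| vs |r_jh| after aligning signs.

    Resistance indices (HOMA-IR, FIRI, fasting insulin) correlate
    negatively with clamp sensitivity while QUICKI and G/I correlate
    positively; comparing predictive strength means comparing |r|.  Both
    correlations are sign-aligned to positive (flipping the implied sign
    of one index flips r_kh accordingly), then the Williams t is applied;
    positive t means |r_jk| > |r_jh|.
    """
    s_k = 1.0 if r_jk >= 0 else -1.0
    s_h = 1.0 if r_jh >= 0 else -1.0
    return steiger_test(s_k * r_jk, s_h * r_jh, s_k * s_h * r_kh, n)


def transformed_robust_correlation(
    x,
    y,
    df: float = 4.0,
    level: float = 0.95,
    transform: bool = True,
) -> CorrelationResult:
    """Box-Cox each margin (lambda chosen per variable), then t-EM correlation.

    The shaping transform requires positive values; each variable is
    shifted above zero if necessary before selecting its lambda (the shift
    is monotone, so ranks and the qualitative association are preserved).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    lam_x = lam_y = None
    if transform:
        xs = _shift_positive(x)
        ys = _shift_positive(y)
        lam_x = boxcox_lambda(xs)
        lam_y = boxcox_lambda(ys)
        xt = boxcox_transform(xs, lam_x)
        yt = boxcox_transform(ys, lam_y)
    else:
        xt, yt = x, y
    _, _, corr = t_cov_em(np.column_stack([xt, yt]), df=df)
    r = float(np.clip(corr[0, 1], -0.999999, 0.999999))
    return correlation_with_ci(r, x.size, level, lam_x, lam_y, method="t_em")


def _shift_positive(x: np.ndarray) -> np.ndarray:
    mn = x.min()
    if mn > 0:
        return x
    return x - mn + 1e-3 * max(np.ptp(x), 1.0)
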