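"""Box-Cox selection, multivariate-t EM correlation, Fisher intervals and the
Steiger-Williams dependent-correlation test."""

import math

import numpy as np
import pytest
from scipy import stats

from clampval import boxcox_lambda, boxcox_transform, corr_ci, steiger_test, t_cov_em
from clampval.exceptions import DomainError, InsufficientDataError
from clampval.robust_stats import compare_correlations_abs, transformed_robust_correlation


# ---------------------------------------------------------------------------
# Box-Cox

@pytest.mark.parametrize(
    "x,lam,expected",
    [(np.array([3.0]), 1.0, [2.0]), (np.array([math.e]), 0.0, [1.0]), (np.array([3.0]), 2.0, [4.0])],
)
def test_boxcox_transform_values(x, lam, expected):
    assert boxcox_transform(x, lam) == pytest.approx(expected)


def test_boxcox_transform_rejects_nonpositive():
    with pytest.raises(DomainError):
        boxcox_transform(np.array([1.0, 0.0]), 0.5)


def test_boxcox_lambda_lognormal_near_zero(rng):
    x = np.exp(rng.standard_normal(10_000))
    lam = boxcox_lambda(x)
    assert -0.05 <= lam <= 0.05


def test_boxcox_lambda_matches_unconstrained_mle(rng):
    x = 100.0 + rng.standard_normal(2000)
    lam = boxcox_lambda(x)
    _, lam_mle = stats.boxcox(x)
    assert abs(lam - lam_mle) <= 0.01 + 1e-9  # within grid resolution


def test_boxcox_lambda_degenerate_inputs():
    with pytest.raises(DomainError):
        boxcox_lambda(np.full(10, 3.0))
    with pytest.raises(InsufficientDataError):
        boxcox_lambda(np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# multivariate-t EM

def test_t_em_large_df_matches_pearson(rng):
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=2000)
    _, _, corr = t_cov_em(X, df=1e6)
    pearson = np.corrcoef(X, rowvar=False)[0, 1]
    assert abs(corr[0, 1] - pearson) < 1e-3


def test_t_em_downweights_gross_outlier(rng):
    cov = np.array([[1.0, 0.7], [0.7, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=500)
    r_clean = np.corrcoef(X, rowvar=False)[0, 1]
    Xc = X.copy()
    Xc[0, 0] *= 50.0
    r_contam = np.corrcoef(Xc, rowvar=False)[0, 1]
    _, _, corr = t_cov_em(Xc, df=4)
    assert abs(corr[0, 1] - r_clean) < abs(r_contam - r_clean)


def test_t_em_affine_equivariance(rng):
    X = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=400)
    _, _, c1 = t_cov_em(X, df=4)
    Y = X.copy()
    Y[:, 0] = 13.0 - 7.0 * Y[:, 0]  # affine rescale flips the sign
    _, _, c2 = t_cov_em(Y, df=4)
    assert c2[0, 1] == pytest.approx(-c1[0, 1], abs=1e-8)


def test_t_em_input_validation(rng):
    X = rng.standard_normal((50, 2))
    X[:, 1] = 3.0
    with pytest.raises(DomainError):
        t_cov_em(X)
    with pytest.raises(DomainError):
        t_cov_em(rng.standard_normal((2, 3)))


# ---------------------------------------------------------------------------
# Fisher-z interval

def test_corr_ci_symmetric_about_zero():
    lo, hi = corr_ci(0.0, 50)
    assert lo == pytest.approx(-hi)


def test_corr_ci_reproduces_reported_intervals():
    lo, hi = corr_ci(-0.30, 79)
    assert round(lo, 2) == -0.49
    # upper bound from the 2-dp rounded r lands within one unit in the
    # last digit of the reported -0.09
    assert hi == pytest.approx(-0.09, abs=0.01)
    lo, hi = corr_ci(0.29, 79)
    assert round(lo, 2) == 0.07
    assert round(hi, 2) == 0.48


def test_corr_ci_width_decreasing_in_n():
    widths = [np.diff(corr_ci(0.4, n))[0] for n in (10, 30, 100, 1000)]
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_corr_ci_validation():
    with pytest.raises(InsufficientDataError):
        corr_ci(0.5, 3)
    with pytest.raises(DomainError):
        corr_ci(1.0, 50)


# ---------------------------------------------------------------------------
# Steiger-Williams test

def _williams_t_oracle(r_jk, r_jh, r_kh, n):
    """Textbook Williams formula, coded independently of the implementation."""
    detR = (1 - r_jk**2 - r_jh**2 - r_kh**2) + 2 * r_jk * r_jh * r_kh
    rbar = 0.5 * (r_jk + r_jh)
    num = (r_jk - r_jh) * math.sqrt((n - 1) * (1 + r_kh))
    den = math.sqrt(
        2 * detR * (n - 1) / (n - 3) + rbar * rbar * (1 - r_kh) ** 3
    )
    return num / den


def test_steiger_zero_under_equal_correlations():
    res = steiger_test(0.4, 0.4, 0.3, 100)
    assert res.t_stat == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 97


def test_steiger_matches_independent_formula():
    res = steiger_test(0.5, 0.3, 0.4, 100)
    assert res.t_stat == pytest.approx(_williams_t_oracle(0.5, 0.3, 0.4, 100), abs=1e-6)
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(res.t_stat), 97), abs=1e-12)


def test_steiger_rejects_inconsistent_triple():
    with pytest.raises(DomainError):
        steiger_test(0.9, 0.9, -0.9, 100)


def test_steiger_sign_alignment_for_resistance_indices():
    # comparing |r|: a resistance index (negative r) vs a sensitivity index
    res_signed = compare_correlations_abs(-0.5, 0.3, -0.4, 100)
    res_aligned = steiger_test(0.5, 0.3, 0.4, 100)
    assert res_signed.t_stat == pytest.approx(res_aligned.t_stat)


def test_steiger_monte_carlo_size(rng):
    """Rejection rate under H0 (equal true correlations) near nominal 0.05."""
    n, reps = 79, 600
    rho = np.array([[1, 0.3, 0.3], [0.3, 1, 0.5], [0.3, 0.5, 1]])
    L = np.linalg.cholesky(rho)
    rej = 0
    for _ in range(reps):
        Z = rng.standard_normal((n, 3)) @ L.T
        C = np.corrcoef(Z, rowvar=False)
        if steiger_test(C[0, 1], C[0, 2], C[1, 2], n).p_value < 0.05:
            rej += 1
    assert 0.02 <= rej / reps <= 0.09


# ---------------------------------------------------------------------------
# combined transform + robust correlation

def test_transformed_robust_correlation_recovers_log_scale_association(rng):
    n = 1500
    z = rng.multivariate_normal([0, 0], [[1, -0.5], [-0.5, 1]], size=n)
    x = np.exp(1.0 + 0.6 * z[:, 0])
    y = np.exp(2.0 + 0.3 * z[:, 1])
    res = transformed_robust_correlation(x, y)
    assert res.r == pytest.approx(-0.5, abs=0.06)
    assert res.ci_low <= res.r <= res.ci_high
    assert abs(res.lambda_x) < 0.25 and abs(res.lambda_y) < 0.25
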