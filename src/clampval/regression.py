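"""Robust multiple linear regression of clamp M on an index plus sex and adiposity.

The M-estimator is Huber's: IRLS with psi truncated at ``tuning`` robust
scale units (1.345 gives 95% efficiency under Gaussian errors) and scale
re-estimated by the normalised median absolute deviation each iteration.
The fit itself is delegated to statsmodels' RLM, which implements exactly
this scheme; this module owns the design construction, the rank/validity
checks and the R^2 convention for robust fits (squared Pearson
correlation of fitted vs observed, stated in all reports since no single
R^2 definition exists for M-estimators).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import ConvergenceError, DomainError


@dataclass(frozen=True)
class RobustFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    scale: float
    r_squared: float
    n: int
    converged: bool
    term_names: tuple
    fitted_values: np.ndarray


def _check_design(X: np.ndarray, term_names: Sequence[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise DomainError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # report which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                bad.append(term_names[j] if j < len(term_names) else f"col{j}")
        raise DomainError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_huber(
    y,
    X,
    tuning: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
    term_names: Optional[Sequence[str]] = None,
) -> RobustFit:
    """Huber M-estimate of the linear model y = X b + e.

    ``X`` must already contain the intercept column.  With
    ``tuning -> inf`` the estimate coincides with ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or len(y) != len(X):
        raise DomainError("y must be 1-D and X 2-D with matching length")
    names = tuple(term_names) if term_names is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    _check_design(X, names)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=max_iter)
    if not getattr(res, "converged", True):
        raise ConvergenceError(f"Huber IRLS did not converge in {max_iter} iterations")
    fitted = np.asarray(res.fittedvalues)
    return RobustFit(
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        scale=float(res.scale),
        r_squared=_fitted_r2(fitted, y),
        n=len(y),
        converged=bool(getattr(res, "converged", True)),
        term_names=names,
        fitted_values=fitted,
    )


def _fitted_r2(fitted: np.ndarray, y: np.ndarray) -> float:
    if np.var(y) == 0:
        raise DomainError("R^2 undefined: zero variance in y")
    if np.var(fitted) == 0:
        return 0.0
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r * r)


def robust_r2(fit: RobustFit, y) -> float:
    """Squared Pearson correlation between fitted and observed values."""
    return _fitted_r2(np.asarray(fit.fitted_values), np.asarray(y, dtype=float))


def build_design(
    index_values,
    sex,
    adiposity=None,
    interaction: bool = False,
    adiposity_names: Optional[Sequence[str]] = None,
    index_name: str = "index",
):
    """Intercept + sex (female=1) + index + adiposity column(s) [+ index x sex].

    ``adiposity`` may be None, one vector, or a list of vectors (for the
    BMI & WC style two-surrogate model); variables are expected already on
    their analysis (e.g. Box-Cox) scales.
    Returns (X, term_names).
    """
    idx = np.asarray(index_values, dtype=float)
    sex = np.asarray(sex)
    if len(sex) != len(idx):
        raise DomainError("index_values and sex have mismatched lengths")
    female = np.where(sex == "F", 1.0, np.where(sex == "M", 0.0, np.nan))
    if np.any(np.isnan(female)):
        raise DomainError("sex must be coded 'M'/'F'")
    cols = [np.ones_like(idx), female, idx]
    names = ["intercept", "sex_female", index_name]
    if adiposity is not None:
        arr = np.asarray(adiposity, dtype=float)
        adip_list = [arr] if arr.ndim == 1 else [arr[j] for j in range(arr.shape[0])]
        if adiposity_names is None:
            adiposity_names = [f"adiposity{j}" for j in range(len(adip_list))]
        for a, nm in zip(adip_list, adiposity_names):
            a = np.asarray(a, dtype=float)
            if len(a) != len(idx):
                raise DomainError(f"adiposity column {nm} has mismatched length")
            cols.append(a)
            names.append(nm)
    if interaction:
        cols.append(idx * female)
        names.append(f"{index_name}:sex_female")
    X = np.column_stack(cols)
    if np.any(~np.isfinite(X)):
        raise DomainError("design matrix contains missing values")
    return X, names
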