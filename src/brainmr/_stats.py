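"""Shared least-squares machinery.

Everything here works on plain numpy arrays.  The association scans use the
Frisch–Waugh–Lovell decomposition: covariates (plus intercept) are reduced to
an orthonormal basis Q once, predictors and responses are residualized against
Q, and the per-variant (or per-region) simple regression on the residuals
reproduces the full multiple-regression coefficient, standard error, and
t-statistic with the correct residual degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CollinearityError, ValidationError

#: relative tolerance below which a residualized predictor counts as constant
_VAR_TOL = 1e-12


def design_matrix(
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] | list[str],
    categorical: set[str] | frozenset[str] = frozenset(),
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept-led design matrix from named covariate columns.

    Categorical covariates are expanded to full-rank indicator contrasts with
    the first observed level dropped.  Raises :class:`CollinearityError`
    naming the redundant columns when the result is rank deficient.
    """
    n = len(phenotypes)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise ValidationError(f"covariate {cov!r} not found in phenotype table")
        col = phenotypes[cov]
        if cov in categorical or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            levels = pd.unique(col.dropna())
            if len(levels) < 2:
                raise ValidationError(
                    f"categorical covariate {cov!r} has <2 observed levels"
                )
            for level in levels[1:]:
                cols.append((col == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style scan
        bad = []
        kept = np.ones((n, 0))
        for j, name in enumerate(names):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(name)
            else:
                kept = trial
        raise CollinearityError(bad or names)
    return X, names


def qr_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of the design matrix."""
    Q, _ = np.linalg.qr(X)
    return Q


def residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project out span(Q) from the columns of A (A may be 1- or 2-D)."""
    return A - Q @ (Q.T @ A)


def scan_predictors(
    y: np.ndarray, D: np.ndarray, Q: np.ndarray, overwrite_d: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of one response on each predictor column separately, plus covariates.

    Parameters
    ----------
    y : (n,) response
    D : (n, m) matrix of predictors, scanned one at a time; a float32 D makes
        the whole scan run in single precision (useful for large simulation
        studies; the default path is float64)
    Q : (n, k) orthonormal covariate basis (intercept included)
    overwrite_d : residualize D in place when it is a caller-owned float buffer

    Returns
    -------
    beta, se, t, p : (m,) arrays; entries are NaN where a residualized
        predictor is (numerically) constant.
    df : residual degrees of freedom, n - k - 1.
    """
    n = y.shape[0]
    k = Q.shape[1]
    df = n - k - 1
    if df <= 0:
        raise ValidationError(f"not enough observations (n={n}) for {k} covariates")
    dtype = D.dtype if D.dtype in (np.float32, np.float64) else np.float64
    Qd = Q.astype(dtype, copy=False)
    y_r = residualize(y.astype(dtype), Qd)
    if overwrite_d and D.dtype == dtype:
        D_r = D
    else:
        D_r = D.astype(dtype, copy=True)
    D_r -= Qd @ (Qd.T @ D_r)
    sxx = np.einsum("ij,ij->j", D_r, D_r, dtype=np.float64)
    sxy = (D_r.T @ y_r).astype(np.float64)
    syy = float(y_r.astype(np.float64) @ y_r.astype(np.float64))
    scale = np.max(sxx) if sxx.size else 0.0
    ok = sxx > _VAR_TOL * max(scale, 1.0)
    beta = np.full(D.shape[1], np.nan)
    se = np.full(D.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = sxy[ok] / sxx[ok]
        sse = syy - beta[ok] * sxy[ok]
        sse = np.clip(sse, 0.0, None)
        se[ok] = np.sqrt(sse / df / sxx[ok])
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return beta, se, t, p, df


def scan_outcomes(
    Y: np.ndarray, x: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of each response column on one shared predictor, plus covariates.

    Symmetric counterpart of :func:`scan_predictors`: the scanned axis is the
    response (e.g. one regression per atlas region).  Returns the statistics
    of the ``x`` term per column of ``Y``.
    """
    n = x.shape[0]
    k = Q.shape[1]
    df = n - k - 1
    if df <= 0:
        raise ValidationError(f"not enough observations (n={n}) for {k} covariates")
    x_r = residualize(x.astype(float), Q)
    sxx = float(x_r @ x_r)
    if sxx <= _VAR_TOL * n:
        raise ValidationError("predictor is constant after covariate adjustment")
    Y = Y.astype(float)
    QtY = Q.T @ Y
    syy = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)
    sxy = x_r @ Y  # x_r' M Y since x_r ⟂ Q
    beta = sxy / sxx
    sse = np.clip(syy - beta * sxy, 0.0, None)
    ok = syy > _VAR_TOL * max(np.max(syy) if syy.size else 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / df / sxx)
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok & (se > 0), se, np.nan)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return beta, se, t, p, df


def partial_correlation(
    a: np.ndarray, b: np.ndarray, Q: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of two vectors after residualizing both on Q.

    Returns ``(r, t, df)`` with df = n - k - 2; equivalent to the t-test of
    the OLS coefficient of ``a`` in ``b ~ a + covariates``.
    """
    n = a.shape[0]
    df = n - Q.shape[1] - 1
    if df <= 1:
        raise ValidationError("not enough observations for partial correlation")
    a_r = residualize(a.astype(float), Q)
    b_r = residualize(b.astype(float), Q)
    na = float(a_r @ a_r)
    nb = float(b_r @ b_r)
    if na <= _VAR_TOL * n or nb <= _VAR_TOL * n:
        raise ValidationError("zero variance after covariate adjustment")
    r = float(a_r @ b_r) / np.sqrt(na * nb)
    r = float(np.clip(r, -1.0, 1.0))
    denom = max(1.0 - r * r, _VAR_TOL)
    t = r * np.sqrt(df / denom)
    return r, float(t), df


def one_tailed_p(t: float, df: int, expected_sign: int) -> float:
    """One-tailed p-value of a t statistic in the direction ``expected_sign``."""
    if expected_sign >= 0:
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Plain OLS: coefficients, standard errors, residual df.

    Small dense problems only (mediation paths); uses the normal equations via
    Cholesky with a lstsq fallback.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValidationError("not enough observations for OLS fit")
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        L = np.linalg.cholesky(XtX)
        beta = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
        XtX_inv_diag = np.diag(np.linalg.inv(XtX))
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        XtX_inv_diag = np.diag(np.linalg.pinv(XtX))
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(sigma2 * XtX_inv_diag, 0.0, None))
    return beta, se, df
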