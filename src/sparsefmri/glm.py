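"""Ordinary-least-squares estimation of the simulation GLM y = Xβ + ε.

Plain OLS, exactly as the simulation specifies: no prewhitening and no
autocorrelation correction.  An intercept is always part of the design (see
:func:`sparsefmri.regressors.assemble_design`); with demeaned task regressors
this leaves the task estimates unchanged while making fits invariant to
baseline offsets in user-supplied data.

Two-sided p-values from the t distribution accompany every t-statistic: with
sparse designs the residual degrees of freedom differ markedly across TR
choices, so equal t values can carry quite different significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, InsufficientSamplesError
from .regressors import DesignMatrix, _collinear_pairs

__all__ = ["GLMResult", "fit_ols", "contrast"]

#: Condition-number ceiling above which a design is treated as rank deficient.
MAX_CONDITION_NUMBER = 1e8


@dataclass(frozen=True)
class GLMResult:
    names: tuple
    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    dof: int
    residuals: np.ndarray
    rss: float
    sigma2: float
    xtx_inv: np.ndarray

    def __getitem__(self, name: str):
        """(beta, se, t, p) for one named column."""
        i = self.names.index(name)
        return self.beta[i], self.se[i], self.tstat[i], self.pvalue[i]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tbeta\tse\tt\tp\tdof\n")
            for i, name in enumerate(self.names):
                fh.write(
                    f"{name}\t{self.beta[i]:.9g}\t{self.se[i]:.9g}\t"
                    f"{self.tstat[i]:.9g}\t{self.pvalue[i]:.9g}\t{self.dof}\n"
                )


def _as_matrix(X):
    if isinstance(X, DesignMatrix):
        return X.matrix, X.names, X.collinear_pairs
    X = np.asarray(X, dtype=float)
    names = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, names, _collinear_pairs(names, X)


def fit_ols(y: np.ndarray, X) -> GLMResult:
    """Fit y = Xβ + ε by ordinary least squares.

    Parameters
    ----------
    y:
        Per-acquisition response vector.
    X:
        A :class:`~sparsefmri.regressors.DesignMatrix` or a plain 2-D array.

    Raises
    ------
    CollinearityError
        If the design is (numerically) rank deficient; the error names the
        near-dependent column pairs when identifiable.
    InsufficientSamplesError
        If fewer than one residual degree of freedom remains.
    """
    y = np.asarray(y, dtype=float)
    mat, names, flagged = _as_matrix(X)
    n, p = mat.shape
    if y.size != n:
        raise ValueError(f"y has length {y.size}, design has {n} rows")
    dof = n - p
    if dof < 1:
        raise InsufficientSamplesError(
            f"{n} acquisitions with {p} columns leave dof={dof} < 1"
        )
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond >= MAX_CONDITION_NUMBER:
        detail = (
            "; near-dependent columns: "
            + ", ".join(f"({a}, {b})" for a, b in flagged)
            if flagged
            else ""
        )
        raise CollinearityError(
            f"design matrix is rank deficient (condition number {cond:.3g})"
            + detail,
            columns=flagged,
        )
    beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
    residuals = y - mat @ beta
    rss = float(residuals @ residuals)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(mat.T @ mat)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return GLMResult(
        names=names,
        beta=beta,
        se=se,
        tstat=tstat,
        pvalue=pvalue,
        dof=dof,
        residuals=residuals,
        rss=rss,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
    )


def contrast(result: GLMResult, weights) -> tuple:
    """Linear contrast wᵀβ with its standard error and t-statistic.

    Returns ``(estimate, se, tstat)``.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(result.names):
        raise ValueError(
            f"{w.size} weights for {len(result.names)} design columns"
        )
    if not np.any(w):
        raise ValueError("contrast weights are all zero")
    estimate = float(w @ result.beta)
    se = float(np.sqrt(result.sigma2 * (w @ result.xtx_inv @ w)))
    if se > 0:
        tstat = estimate / se
    else:  # exact fit: zero estimate is exactly zero, anything else is exact
        tstat = 0.0 if estimate == 0.0 else math.copysign(math.inf, estimate)
    return estimate, se, tstat
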