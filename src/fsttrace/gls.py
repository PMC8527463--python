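"""Generalized least squares for population-specific F_ST.

Population-specific F_ST estimates of related populations are
correlated, so ordinary least squares overstates precision when
regressing them on environmental covariates.  With the jackknife
covariance Ω̂ of the estimates,

    psF_ST^i = β0 + β1 x1i + ... + βs xsi + εi,   ε ~ N(0, Ω),

GLS gives β̂ = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹y with var(β̂) = (XᵀΩ⁻¹X)⁻¹.  Ω is
treated as known, so Z = β̂/se(β̂) is referred to the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .estimators import nearest_psd

__all__ = ["GlsFit", "gls_fit", "screen_collinear"]


@dataclass
class GlsFit:
    """GLS coefficients with SEs, Z statistics and two-sided normal p."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    cov_beta: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Variable": self.names, "Estimate": self.beta, "SE": self.se,
            "Z": self.z, "P": self.p,
        })


def _repair_spd(omega: np.ndarray, rel_tol: float = 1e-10) -> np.ndarray:
    """Clip tiny/negative eigenvalues and jitter so Cholesky succeeds."""
    omega = nearest_psd(omega)
    w = np.linalg.eigvalsh(omega)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("omega has no positive eigenvalue")
    floor = rel_tol * wmax
    if w.min() < floor:
        omega = omega + floor * np.eye(omega.shape[0])
    return omega


def gls_fit(y, x, omega, names: Optional[Sequence[str]] = None,
            add_intercept: bool = True) -> GlsFit:
    """Fit the GLS regression of y on x with residual covariance omega.

    ``x`` may be a DataFrame (column names kept) or array.  An intercept
    column is prepended unless ``add_intercept=False``.  Raises on a
    singular design, naming the collinear columns.
    """
    if isinstance(x, pd.DataFrame):
        if names is None:
            names = list(x.columns)
        x = x.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1 and len(np.asarray(y)) == x.shape[1]:
            x = x.T
        if names is None:
            names = [f"x{j + 1}" for j in range(x.shape[1])]
    names = list(names)
    y = np.asarray(y, dtype=float)
    if add_intercept:
        x = np.column_stack([np.ones(len(y)), x])
        names = ["(Intercept)"] + names
    n, k = x.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (n, n):
        raise ValueError("omega must be n x n")
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("omega must be symmetric")
    omega = _repair_spd(omega)

    # whiten with the Cholesky factor: solve L w = v
    c, low = linalg.cho_factor(omega, lower=True)
    xw = linalg.solve_triangular(c, x, lower=True)
    yw = linalg.solve_triangular(c, y, lower=True)

    r = np.linalg.matrix_rank(xw)
    if r < k:
        _, rr, piv = linalg.qr(xw, pivoting=True, mode="economic")
        dropped = sorted(names[j] for j in piv[r:])
        raise ValueError(f"design matrix is singular; collinear columns: {dropped}")

    xtx = xw.T @ xw
    cov_beta = linalg.cho_solve(linalg.cho_factor(xtx), np.eye(k))
    beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    resid = y - x @ beta
    return GlsFit(names, beta, se, z, p, resid, cov_beta)


def correlation_critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for a Pearson correlation with n samples."""
    if n < 3:
        raise ValueError("need at least 3 rows")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def screen_collinear(x: pd.DataFrame, r_threshold: Optional[float] = None,
                     alpha: float = 0.05):
    """Advisory collinearity screen on a covariate table.

    Repeatedly drops the covariate with the most pairwise correlations
    exceeding the threshold (default: the two-sided significance
    critical |r| at ``alpha``) until none exceed.  Ties go to the
    covariate with the larger summed |r|, then to the later column.
    Returns ``(retained_columns, correlation_table)``.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least two covariates")
    if r_threshold is None:
        r_threshold = correlation_critical_r(len(x), alpha)
    corr = x.corr()
    cols = list(x.columns)
    while True:
        sub = corr.loc[cols, cols].to_numpy()
        viol = (np.abs(sub) > r_threshold) & ~np.eye(len(cols), dtype=bool)
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = np.flatnonzero(counts == counts.max())
        strength = np.abs(np.where(viol, sub, 0.0)).sum(axis=1)
        drop = worst[np.lexsort((-(np.arange(len(cols))[worst]),
                                 -strength[worst]))][0]
        cols.pop(int(drop))
    return cols, corr
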