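"""Ordinary least squares with full parameter covariance.

Several modules need delta-method standard errors on functions of the
(intercept, slope) pair, which requires the off-diagonal covariance term
that :func:`scipy.stats.linregress` does not expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class OLSResult:
    intercept: float
    slope: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    r_squared: float
    n: int

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def ols(x, y, weights=None) -> OLSResult:
    """Fit y = a + b*x by (optionally weighted) least squares.

    Parameters
    ----------
    x, y : array-like, same length, >= 2 points (>= 3 for a finite SE).
    weights : optional array of inverse-variance weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 points for a line fit, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the regressor")
    X = np.column_stack([np.ones(n), x])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    cov = s2 * xtx_inv
    ss_tot = float(((yw - yw.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return OLSResult(float(beta[0]), float(beta[1]), cov, r2, n)
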