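"""Shared ordinary-least-squares kernel.

Both component regressions of the double-regression estimator (x on
treatment over all patients; y on x and treatment over Phase III patients)
run through :func:`ols_fit`, so their coefficient covariances come from a
single, well-tested place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CollinearityError


@dataclass
class RegressionFit:
    """Least-squares fit summary.

    ``params`` holds the named coefficient estimates, ``cov`` their estimated
    covariance matrix (``resid_variance * (X'X)^{-1}``), ``resid_variance``
    the unbiased residual variance (RSS / df) and ``df`` the residual degrees
    of freedom.
    """

    params: pd.Series
    cov: pd.DataFrame
    resid_variance: float
    df: int
    nobs: int

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))


def ols_fit(
    response: np.ndarray,
    predictors: Sequence[np.ndarray],
    names: Sequence[str],
    intercept: bool = True,
) -> RegressionFit:
    """Fit ``response`` on ``predictors`` (plus an intercept by default).

    Raises
    ------
    CollinearityError
        If the design matrix is singular.
    ValueError
        If there are fewer rows than parameters + 1.
    """
    y = np.asarray(response, dtype=float)
    cols = [np.asarray(p, dtype=float) for p in predictors]
    if len(cols) != len(names):
        raise ValueError("predictors and names must have equal length")
    if intercept:
        cols = [np.ones_like(y)] + cols
        names = ["const"] + list(names)
    X = np.column_stack(cols)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} parameters, got {n}")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("singular design matrix") from exc
    # guard against numerically singular designs that invert without error
    if np.linalg.cond(xtx) > 1e12:
        raise CollinearityError("design matrix is (numerically) singular")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    cov = s2 * xtx_inv
    idx = pd.Index(names)
    return RegressionFit(
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        resid_variance=s2,
        df=df,
        nobs=n,
    )
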