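"""Ordinary-least-squares primitive shared by the scan and interaction stages.

A thin, fast OLS with the exact quantities the likelihood-ratio test
needs (RSS, Gaussian log-likelihood, R², coefficient standard errors)
and explicit degenerate statuses instead of exceptions, so batch runs
never abort on a bad model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: RSS at or below this (relative to total sum of squares, floored
#: absolutely) is treated as a perfect fit.
_RSS_TINY = 1e-12

STATUS_OK = "ok"
STATUS_COLLINEAR = "collinear"
STATUS_INSUFFICIENT_N = "insufficient_n"


@dataclass
class LinearFit:
    """One OLS fit: coefficients, fit quality, Gaussian log-likelihood."""

    coef: np.ndarray
    se: np.ndarray
    rss: float
    r2: float
    loglik: float
    n: int
    n_params: int
    status: str
    perfect_fit: bool = False

    @property
    def df_resid(self) -> int:
        return self.n - self.n_params

    def t_pvalues(self) -> np.ndarray:
        """Two-sided t-test p-values per coefficient."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.coef / self.se
        return 2.0 * stats.t.sf(np.abs(t), self.df_resid)


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood of an OLS fit: -(n/2)(ln(2*pi*RSS/n)+1)."""
    if rss <= 0:
        return np.inf
    return -(n / 2.0) * (np.log(2.0 * np.pi * rss / n) + 1.0)


def fit_linear(y: np.ndarray, X: np.ndarray) -> LinearFit:
    """OLS of ``y`` on design ``X`` (caller supplies the intercept column).

    Rank-deficient designs return ``status='collinear'`` and fits with
    fewer rows than columns ``status='insufficient_n'``; both carry NaN
    coefficients rather than raising, so batch tests can record them.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    nan_fit = LinearFit(
        np.full(p, np.nan), np.full(p, np.nan), np.nan, np.nan, np.nan, n, p,
        STATUS_OK,
    )
    if n <= p:
        nan_fit.status = STATUS_INSUFFICIENT_N
        return nan_fit
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        nan_fit.status = STATUS_COLLINEAR
        return nan_fit
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    perfect = rss <= max(_RSS_TINY, _RSS_TINY * tss)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return LinearFit(
        coef=coef,
        se=se,
        rss=rss,
        r2=r2,
        loglik=np.inf if perfect else gaussian_loglik(rss, n),
        n=n,
        n_params=p,
        status=STATUS_OK,
        perfect_fit=perfect,
    )
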