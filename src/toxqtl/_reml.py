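"""Restricted maximum likelihood (REML) internals.

Two entry points:

* :func:`fit_delta` — profile REML for a single-random-effect model
  ``y = Xb + u + e`` with ``Var(u) = s2g * K``, worked in the eigenbasis of
  ``K`` so each likelihood evaluation is O(n).  Used per marker by the
  mixed-model association scan and for single-kinship heritability.
* :func:`reml_loglik_general` — dense REML log-likelihood for an arbitrary
  covariance ``V``; used for two-kinship variance-component fits where no
  joint eigenbasis exists.

The profiled parameter is ``delta = s2g / s2e``; the residual scale is
profiled out analytically.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

_LOG_DELTA_GRID = np.linspace(-10.0, 10.0, 41)
_JITTER = 1e-6  # ridge added to kinship diagonals for PSD safety


def kinship_eigen(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a kinship matrix with a small PSD jitter."""
    d, U = np.linalg.eigh(K + _JITTER * np.eye(K.shape[0]))
    return np.maximum(d, 0.0), U


def _profile_stats(log_delta: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray):
    """GLS pieces for V = delta*diag(d) + I in the rotated basis."""
    delta = np.exp(log_delta)
    w = delta * d + 1.0
    Xw = Xr / w[:, None]
    XtViX = Xr.T @ Xw
    XtViy = Xw.T @ yr
    beta = np.linalg.solve(XtViX, XtViy)
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    return delta, w, XtViX, beta, rss


def _neg_reml(log_delta: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray) -> float:
    n, q = Xr.shape
    _, w, XtViX, _, rss = _profile_stats(log_delta, yr, Xr, d)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - q)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - q) * np.log(2 * np.pi * sigma2) + np.log(w).sum()
                 + logdet_xvx + (n - q))
    return -ll


def fit_delta(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray):
    """Maximize the profiled REML over log-delta (coarse grid + refinement).

    Returns ``(delta, sigma2_e, beta, XtViX_inv, loglik)`` where ``sigma2_e``
    is the REML residual variance and the genetic variance is
    ``delta * sigma2_e``.
    """
    vals = [_neg_reml(ld, yr, Xr, d) for ld in _LOG_DELTA_GRID]
    i = int(np.argmin(vals))
    lo = _LOG_DELTA_GRID[max(i - 1, 0)]
    hi = _LOG_DELTA_GRID[min(i + 1, len(_LOG_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        _neg_reml, bounds=(lo, hi), args=(yr, Xr, d), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if res.fun <= vals[i] else float(_LOG_DELTA_GRID[i])
    delta, w, XtViX, beta, rss = _profile_stats(log_delta, yr, Xr, d)
    n, q = Xr.shape
    sigma2 = rss / (n - q)
    # treat the grid edges as a boundary estimate of delta ~ 0 / infinity
    if log_delta <= _LOG_DELTA_GRID[0] + 1e-9:
        delta = 0.0
    return delta, sigma2, beta, np.linalg.inv(XtViX), -_neg_reml(log_delta, yr, Xr, d)


def reml_loglik_general(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """REML log-likelihood with the residual scale profiled out.

    ``V`` is the covariance shape (total covariance = sigma2 * V).  Returns
    ``(loglik, sigma2, beta)``.
    """
    n, q = X.shape
    try:
        c = linalg.cho_factor(V + _JITTER * np.eye(n), lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan, np.full(q, np.nan)
    logdet_v = 2.0 * np.log(np.diag(c[0])).sum()
    ViX = linalg.cho_solve(c, X)
    Viy = linalg.cho_solve(c, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve(c, r))
    if rss <= 0:
        return -np.inf, 0.0, beta
    sigma2 = rss / (n - q)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, sigma2, beta
    ll = -0.5 * ((n - q) * np.log(2 * np.pi * sigma2) + logdet_v
                 + logdet_xvx + (n - q))
    return ll, sigma2, beta
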