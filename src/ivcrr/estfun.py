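"""Profiled one-dimensional GMM/SMM estimating functions.

Two moment-condition systems estimate the same log causal risk ratio beta1:

* multiplicative-error GMM (MGMM), whose two conditions
  ``sum_i y_i exp(-b1 x_i) - b0 = 0`` and
  ``sum_i g_i (y_i exp(-b1 x_i) - b0) = 0``
  profile exactly to the single SMM estimating equation

      f_M(b1) = sum_i y_i exp(-b1 x_i) (g_i - gbar) = 0 ;

* additive-error GMM (LGMM), ``sum_i y_i - exp(b0' + b1 x_i) = 0`` and
  ``sum_i g_i (y_i - exp(b0' + b1 x_i)) = 0``, whose first condition gives
  ``exp(b0') = (sum y_i) / (sum exp(b1 x_i))`` and hence

      f_L(b1) = sum_i g_i y_i
                - (sum_i y_i) * (sum_i g_i exp(b1 x_i)) / (sum_i exp(b1 x_i)).

Both are evaluated in sign/log space so that the identification scan over
``|b1| <= 50`` never overflows.  Only individuals with ``y_i = 1`` enter the
multiplicative sum, which the grid scanner exploits.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .data import DegenerateDataError, IVData
from .signedlog import (
    CANCELLATION_LOG_EPS,
    SignedLogValue,
    combine_pos_neg_arrays,
    signed_logsumexp,
)

__all__ = [
    "MethodKind",
    "mgmm_estfun",
    "lgmm_estfun",
    "mgmm_beta0",
    "lgmm_beta0prime",
    "estfun",
    "estfun_grid",
]

# grid chunk sized so the working matrix stays around 100 MB even at n = 10^6
_CHUNK_BUDGET = 12_000_000


class MethodKind(str, Enum):
    """Which moment-condition system to use."""

    MGMM = "mgmm"
    LGMM = "lgmm"

    @classmethod
    def coerce(cls, value) -> "MethodKind":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


def _mgmm_terms(ds: IVData):
    """Weights and exposures of the event (y=1) individuals only."""
    gbar = float(ds.g.mean())
    mask = ds.y == 1
    return ds.g[mask] - gbar, ds.x[mask]


def mgmm_estfun(ds: IVData, beta1: float) -> SignedLogValue:
    """Multiplicative (SMM-profiled) estimating function at ``beta1``.

    Returns exact zero for every ``beta1`` when no events are observed: an
    identically-zero function carries no information, which the scan layer
    flags as degenerate rather than treating as a solution.
    """
    w, x1 = _mgmm_terms(ds)
    if w.size == 0:
        return SignedLogValue.zero()
    return signed_logsumexp(w, -float(beta1) * x1)


def lgmm_estfun(ds: IVData, beta1: float) -> SignedLogValue:
    """Additive-error (LGMM-profiled) estimating function at ``beta1``."""
    y = ds.y.astype(float)
    n_events = float(y.sum())
    if n_events == 0:
        return SignedLogValue.zero()
    a = float(np.dot(ds.g, y))
    t = _exposure_weighted_mean_g(ds.g, ds.x, np.array([float(beta1)]))[0]
    f = a - n_events * t
    if abs(f) <= CANCELLATION_LOG_EPS * (abs(a) + abs(n_events * t)):
        return SignedLogValue.zero()
    return SignedLogValue.from_value(f)


def _exposure_weighted_mean_g(g, x, beta1s) -> np.ndarray:
    """``sum g_i exp(b x_i) / sum exp(b x_i)`` for each b, shift-stabilised.

    The common exponential shift cancels in the ratio, so the result is an
    ordinary float bounded by max|g| for any b.
    """
    bx = x[:, None] * beta1s[None, :]
    bx -= bx.max(axis=0, keepdims=True)
    e = np.exp(bx)
    return (g @ e) / e.sum(axis=0)


def mgmm_beta0(ds: IVData, beta1: float) -> float:
    """Profiled multiplicative intercept ``(1/n) sum y_i exp(-b1 x_i)``.

    This is the outcome probability at x = 0; it equals the sample prevalence
    at ``beta1 = 0`` and is 0 when no events are observed.
    """
    mask = ds.y == 1
    if not mask.any():
        return 0.0
    ls = float(logsumexp(-float(beta1) * ds.x[mask]))
    lv = ls - math.log(ds.n)
    return math.inf if lv > math.log(np.finfo(float).max) else math.exp(lv)


def lgmm_beta0prime(ds: IVData, beta1: float) -> float:
    """Profiled additive-model intercept ``ln(sum y) - ln(sum exp(b1 x))``."""
    n_events = ds.n_events
    if n_events == 0:
        raise DegenerateDataError("beta0' is undefined when y has no events")
    return math.log(n_events) - float(logsumexp(float(beta1) * ds.x))


def estfun(ds: IVData, method, beta1: float) -> SignedLogValue:
    """Dispatch to the requested method's profiled estimating function."""
    method = MethodKind.coerce(method)
    if method is MethodKind.MGMM:
        return mgmm_estfun(ds, beta1)
    return lgmm_estfun(ds, beta1)


def _mgmm_grid(ds: IVData, beta1s: np.ndarray):
    w, x1 = _mgmm_terms(ds)
    signs = np.zeros(beta1s.size, dtype=np.int8)
    logmags = np.full(beta1s.size, -math.inf)
    if w.size == 0:
        return signs, logmags
    pos = w > 0
    neg = w < 0
    with np.errstate(divide="ignore"):
        lwp = np.log(w[pos])
        lwn = np.log(-w[neg])
    xp, xn = x1[pos], x1[neg]
    chunk = max(1, _CHUNK_BUDGET // max(1, w.size))
    for lo in range(0, beta1s.size, chunk):
        b = beta1s[lo : lo + chunk]
        log_pos = (
            logsumexp(lwp[:, None] - xp[:, None] * b[None, :], axis=0)
            if xp.size
            else np.full(b.size, -math.inf)
        )
        log_neg = (
            logsumexp(lwn[:, None] - xn[:, None] * b[None, :], axis=0)
            if xn.size
            else np.full(b.size, -math.inf)
        )
        s, m = combine_pos_neg_arrays(np.atleast_1d(log_pos), np.atleast_1d(log_neg))
        signs[lo : lo + chunk] = s
        logmags[lo : lo + chunk] = m
    return signs, logmags


def _lgmm_grid(ds: IVData, beta1s: np.ndarray):
    y = ds.y.astype(float)
    n_events = float(y.sum())
    signs = np.zeros(beta1s.size, dtype=np.int8)
    logmags = np.full(beta1s.size, -math.inf)
    if n_events == 0:
        return signs, logmags
    a = float(np.dot(ds.g, y))
    chunk = max(1, _CHUNK_BUDGET // ds.n)
    for lo in range(0, beta1s.size, chunk):
        b = beta1s[lo : lo + chunk]
        t = _exposure_weighted_mean_g(ds.g, ds.x, b)
        f = a - n_events * t
        zero = np.abs(f) <= CANCELLATION_LOG_EPS * (np.abs(a) + np.abs(n_events * t))
        f[zero] = 0.0
        signs[lo : lo + chunk] = np.sign(f).astype(np.int8)
        with np.errstate(divide="ignore"):
            logmags[lo : lo + chunk] = np.where(zero, -math.inf, np.log(np.abs(f)))
    return signs, logmags


def estfun_grid(ds: IVData, method, beta1s: np.ndarray):
    """Vectorised scan support: ``(signs, logmags)`` over a beta1 grid.

    Pointwise consistent with :func:`estfun` (same shift-and-reduce
    arithmetic and the same exact-zero cancellation rule).
    """
    method = MethodKind.coerce(method)
    beta1s = np.asarray(beta1s, dtype=float)
    if method is MethodKind.MGMM:
        return _mgmm_grid(ds, beta1s)
    return _lgmm_grid(ds, beta1s)
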