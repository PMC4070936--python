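"""Sign / log-magnitude arithmetic for estimating-function evaluation.

The GMM/SMM estimating functions for the causal risk ratio contain terms of
the form ``w_i * exp(c * x_i)`` that overflow double precision long before the
diagnostic scan range ``|beta1| <= 50`` is exhausted (the exponent can exceed
200).  All sums of such terms are therefore carried as a sign together with
the natural log of the absolute value, and only reconstituted as ordinary
floats when they are known to be representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

#: Positive and negative parts whose log-magnitudes agree to within this
#: absolute log-difference are declared to cancel exactly.  This makes sign
#: counting deterministic at the double-precision limit.
CANCELLATION_LOG_EPS = 1e-14

_LOG_FLOAT_MAX = math.log(np.finfo(float).max)


@dataclass(frozen=True)
class SignedLogValue:
    """A real number stored as ``sign * exp(logmag)``.

    ``sign == 0`` represents exact zero, with ``logmag = -inf`` by convention.
    """

    sign: int
    logmag: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign!r}")
        if self.sign == 0 and self.logmag != -math.inf:
            object.__setattr__(self, "logmag", -math.inf)
        if math.isnan(self.logmag):
            raise ValueError("logmag must not be NaN")

    @classmethod
    def from_value(cls, value: float) -> "SignedLogValue":
        value = float(value)
        if math.isnan(value):
            raise ValueError("cannot represent NaN")
        if value == 0.0:
            return cls(0, -math.inf)
        return cls(1 if value > 0 else -1, math.log(abs(value)))

    @classmethod
    def zero(cls) -> "SignedLogValue":
        return cls(0, -math.inf)

    @property
    def value(self) -> float:
        """Reconstituted float; overflows to ``+-inf`` beyond float range."""
        if self.sign == 0:
            return 0.0
        if self.logmag > _LOG_FLOAT_MAX:
            return math.inf * self.sign
        return self.sign * math.exp(self.logmag)

    @property
    def overflows(self) -> bool:
        return self.sign != 0 and self.logmag > _LOG_FLOAT_MAX

    def __neg__(self) -> "SignedLogValue":
        return SignedLogValue(-self.sign, self.logmag)


def _combine_pos_neg(log_pos: float, log_neg: float) -> SignedLogValue:
    """Difference ``exp(log_pos) - exp(log_neg)`` in sign/log form."""
    if log_pos == -math.inf and log_neg == -math.inf:
        return SignedLogValue.zero()
    if log_neg == -math.inf:
        return SignedLogValue(1, log_pos)
    if log_pos == -math.inf:
        return SignedLogValue(-1, log_neg)
    d = log_pos - log_neg
    if abs(d) < CANCELLATION_LOG_EPS:
        return SignedLogValue.zero()
    if d > 0:
        return SignedLogValue(1, log_pos + math.log1p(-math.exp(-d)))
    return SignedLogValue(-1, log_neg + math.log1p(-math.exp(d)))


def signed_logsumexp(weights, exponents) -> SignedLogValue:
    """Evaluate ``sum_i weights_i * exp(exponents_i)`` without overflow.

    Positive- and negative-weight terms are reduced separately with the
    log-sum-exp shift and combined by log-difference; cancellation closer
    than :data:`CANCELLATION_LOG_EPS` in log-magnitude yields exact zero.
    An empty input is exact zero.  NaN anywhere is a numeric error.
    """
    w = np.asarray(weights, dtype=float)
    e = np.asarray(exponents, dtype=float)
    if w.shape != e.shape or w.ndim != 1:
        raise ValueError("weights and exponents must be equal-length 1-d arrays")
    if w.size == 0:
        return SignedLogValue.zero()
    if np.isnan(w).any() or np.isnan(e).any():
        raise ValueError("NaN in signed_logsumexp input")

    with np.errstate(divide="ignore"):
        pos = w > 0
        neg = w < 0
        log_pos = float(logsumexp(np.log(w[pos]) + e[pos])) if pos.any() else -math.inf
        log_neg = float(logsumexp(np.log(-w[neg]) + e[neg])) if neg.any() else -math.inf
    return _combine_pos_neg(log_pos, log_neg)


def combine_pos_neg_arrays(log_pos: np.ndarray, log_neg: np.ndarray):
    """Vectorised :func:`_combine_pos_neg` over arrays.

    Returns ``(signs, logmags)`` with the identical cancellation rule, used by
    the grid scanners where thousands of grid points are reduced at once.
    """
    log_pos = np.asarray(log_pos, dtype=float)
    log_neg = np.asarray(log_neg, dtype=float)
    signs = np.zeros(log_pos.shape, dtype=np.int8)
    logmags = np.full(log_pos.shape, -math.inf)

    both_ninf = np.isneginf(log_pos) & np.isneginf(log_neg)
    with np.errstate(invalid="ignore"):
        d = log_pos - log_neg
    d[both_ninf] = 0.0  # marked zero below

    pos_only = np.isneginf(log_neg) & ~np.isneginf(log_pos)
    neg_only = np.isneginf(log_pos) & ~np.isneginf(log_neg)
    mixed = ~both_ninf & ~pos_only & ~neg_only

    signs[pos_only] = 1
    logmags[pos_only] = log_pos[pos_only]
    signs[neg_only] = -1
    logmags[neg_only] = log_neg[neg_only]

    live = mixed & (np.abs(d) >= CANCELLATION_LOG_EPS)
    signs[live] = np.where(d[live] > 0, 1, -1)
    with np.errstate(divide="ignore"):
        logmags[live] = np.maximum(log_pos[live], log_neg[live]) + np.log1p(
            -np.exp(-np.abs(d[live]))
        )
    return signs, logmags
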