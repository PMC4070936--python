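"""Log-link binomial regression by Fisher scoring with step-halving.

Relative-risk regression models ``P(y=1 | z) = exp(z' beta)`` directly.  The
log link does not keep fitted probabilities below 1, so plain IRLS can step
outside the parameter space; each scoring step is therefore halved until the
linear predictor stays negative and the deviance does not increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConvergenceError", "LogBinomialFit", "fit_log_binomial"]

_ETA_CAP = -1e-10  # linear predictor must stay strictly below 0 (p < 1)


class ConvergenceError(RuntimeError):
    """Log-link fit failed; carries the iteration diagnostics."""

    def __init__(self, message: str, *, n_iter: int, deviance: float, params):
        super().__init__(
            f"{message} (iterations={n_iter}, deviance={deviance:.6g}, "
            f"params={np.asarray(params).round(6).tolist()})"
        )
        self.n_iter = n_iter
        self.deviance = deviance
        self.params = np.asarray(params)


@dataclass(frozen=True)
class LogBinomialFit:
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float
    n_iter: int

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y == 1, -np.log(p), 0.0)
        t2 = np.where(y == 0, -np.log1p(-p), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def fit_log_binomial(
    y,
    X,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogBinomialFit:
    """Fit ``P(y=1) = exp(X beta)`` for binary ``y``.

    Parameters
    ----------
    y : (n,) array of {0,1}
    X : (n, p) design matrix (include the intercept column explicitly).
    max_iter, tol : scoring iteration cap and deviance-change tolerance.

    Raises
    ------
    ConvergenceError
        If the deviance has not stabilised within ``max_iter`` iterations or
        a scoring step cannot be made admissible (e.g. fitted probabilities
        pushed to 1, as under perfect separation).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with n matching y")
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ConvergenceError(
            "outcome is constant; log-link model is undefined",
            n_iter=0, deviance=math.nan, params=np.zeros(X.shape[1]),
        )

    beta = np.zeros(X.shape[1])
    beta[0] = math.log(ybar)  # valid start iff X[:,0] is the intercept
    eta = X @ beta
    if eta.max() >= 0:
        eta = np.minimum(eta, _ETA_CAP)
        beta = np.linalg.lstsq(X, eta, rcond=None)[0]
        eta = X @ beta
    p = np.exp(eta)
    dev = _deviance(y, p)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = p / (1.0 - p)
        z = eta + (y - p) / p
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ xw, xw.T @ z)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular weighted information matrix",
                n_iter=n_iter, deviance=dev, params=beta,
            ) from None
        step = beta_new - beta
        lam = 1.0
        while True:
            cand = beta + lam * step
            eta_c = X @ cand
            if eta_c.max() < _ETA_CAP:
                p_c = np.exp(eta_c)
                dev_c = _deviance(y, p_c)
                if dev_c <= dev + 1e-12:
                    break
            lam *= 0.5
            if lam < 1e-12:
                raise ConvergenceError(
                    "no admissible step (fitted probabilities at the boundary)",
                    n_iter=n_iter, deviance=dev, params=beta,
                )
        beta, eta, p = cand, eta_c, p_c
        if abs(dev - dev_c) < tol:
            dev = dev_c
            break
        dev = dev_c
    else:
        raise ConvergenceError(
            "deviance did not stabilise", n_iter=max_iter, deviance=dev, params=beta
        )

    if eta.max() > -1e-6:
        # a fitted probability has been driven to the boundary p = 1; the
        # "converged" parameters are an artefact (e.g. perfect separation)
        raise ConvergenceError(
            "fitted probability at the boundary p = 1 (separation?)",
            n_iter=n_iter, deviance=dev, params=beta,
        )
    w = p / (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ConvergenceError(
            "information matrix not invertible at the optimum",
            n_iter=n_iter, deviance=dev, params=beta,
        ) from None
    return LogBinomialFit(params=beta, cov_params=cov, deviance=dev, n_iter=n_iter)
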