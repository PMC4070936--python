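"""Model / Results classes for causal risk ratio IV estimation.

Three estimators of the log causal risk ratio ``beta1`` are provided, each as
a small model object whose ``fit()`` returns a results object with the
estimate, its uncertainty and a ``summary()``:

* :class:`RiskRatioGMM` — the semiparametric multiplicative (MGMM/SMM) or
  additive (LGMM) moment-condition estimator, fitted by scanning the profiled
  estimating function and refining its roots.  The identification status of
  the scan (no solution / unique / multiple) is a first-class output: with a
  weak instrument a point estimate without that flag is meaningless.
* :class:`TwoStageRiskRatio` — the parametric comparator: OLS of exposure on
  instrument, then log-link binomial regression of the outcome on the fitted
  exposure.
* :class:`RatioIV` — the ratio (Wald) estimator: log-link slope of outcome on
  instrument divided by the OLS slope of exposure on instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .data import DegenerateDataError, IVData
from .estfun import (
    MethodKind,
    estfun,
    lgmm_beta0prime,
    mgmm_beta0,
)
from .glm import ConvergenceError, fit_log_binomial
from .identification import GridSpec, IdentificationStatus, ScanResult, scan

__all__ = [
    "StrengthStats",
    "instrument_strength",
    "iv_outcome_association",
    "RiskRatioGMM",
    "RiskRatioGMMResults",
    "TwoStageRiskRatio",
    "RatioIV",
    "ParametricIVResults",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class StrengthStats:
    """First-stage instrument strength: R^2 and its F statistic."""

    r2: float
    f_stat: float
    n: int


def instrument_strength(ds: IVData) -> StrengthStats:
    """OLS of exposure on instrument: returns R^2 and F = (n-2) R^2/(1-R^2)."""
    if ds.n < 3:
        raise ValueError("instrument strength needs n >= 3")
    if ds.g_is_constant:
        raise DegenerateDataError("instrument is constant")
    res = sm.OLS(ds.x, sm.add_constant(ds.g)).fit()
    r2 = float(res.rsquared)
    f = math.inf if r2 >= 1.0 else (ds.n - 2) * r2 / (1.0 - r2)
    return StrengthStats(r2=r2, f_stat=f, n=ds.n)


def iv_outcome_association(ds: IVData) -> tuple[float, float]:
    """Wald test of the instrument-outcome association (log-link model).

    This is the test the identification literature recommends reporting when
    the causal parameter itself is poorly identified: it needs no structural
    model for the exposure effect.  Returns ``(z_statistic, p_value)``.
    """
    fit = fit_log_binomial(ds.y, np.column_stack([np.ones(ds.n), ds.g]))
    z = float(fit.params[1] / fit.bse[1])
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _first_stage(ds: IVData):
    if ds.g_is_constant:
        raise DegenerateDataError("instrument is constant")
    res = sm.OLS(ds.x, sm.add_constant(ds.g)).fit()
    return res


class _ResultsBase:
    """Shared presentation for all estimator results."""

    @property
    def crr(self) -> float:
        return math.exp(self.beta1)

    def conf_int(self, alpha: float = 0.05):
        """(lo, hi) for beta1; ``(nan, nan)`` when no SE is available."""
        if self.se is None:
            return (math.nan, math.nan)
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.beta1 - z * self.se, self.beta1 + z * self.se)

    def crr_conf_int(self, alpha: float = 0.05):
        lo, hi = self.conf_int(alpha)
        return (math.exp(lo), math.exp(hi))

    def to_dict(self) -> dict:
        lo, hi = self.crr_conf_int()
        return {
            "method": self.method_label,
            "beta1_hat": self.beta1,
            "crr_hat": self.crr,
            "se": self.se,
            "ci_low": None if math.isnan(lo) else lo,
            "ci_high": None if math.isnan(hi) else hi,
            "multiplicity_flag": self.multiplicity_flag,
            "objective_minimum": getattr(self, "objective_minimum", None),
        }


class RiskRatioGMM:
    """Semiparametric GMM/SMM model for the causal risk ratio.

    Parameters
    ----------
    data : IVData
    method : {"mgmm", "lgmm"} or MethodKind
        Multiplicative-error or additive-error moment conditions.
    """

    def __init__(self, data: IVData, method="mgmm"):
        self.data = data
        self.method = MethodKind.coerce(method)

    def estimating_function(self, beta1: float):
        """Profiled estimating function as a :class:`SignedLogValue`."""
        return estfun(self.data, self.method, beta1)

    def scan(self, grid: GridSpec | None = None) -> ScanResult:
        return scan(self.data, self.method, grid)

    def nuisance_intercept(self, beta1: float) -> float:
        if self.method is MethodKind.MGMM:
            return mgmm_beta0(self.data, beta1)
        return lgmm_beta0prime(self.data, beta1)

    def fit(self, grid: GridSpec | None = None) -> "RiskRatioGMMResults":
        """Scan, refine roots, and assemble the estimate.

        With one or more roots, ``beta1`` is the root of smallest magnitude
        (ties broken toward the smaller value) and the multiplicity flag
        records whether it was unique.  With no root, the squared scaled
        estimating function is minimised over the grid and polished locally,
        mirroring what automated GMM optimisers silently do.
        """
        if grid is None:
            grid = GridSpec()
        sr = self.scan(grid)
        objective_minimum = None
        if sr.roots.size:
            order = sorted(sr.roots, key=lambda r: (abs(r), r))
            beta1 = float(order[0])
        else:
            beta1, objective_minimum = self._minimise_objective(sr)
        se = self._sandwich_se(beta1)
        return RiskRatioGMMResults(
            model=self,
            beta1=beta1,
            se=se,
            scan_result=sr,
            objective_minimum=objective_minimum,
        )

    def _minimise_objective(self, sr: ScanResult):
        """Minimise ``(f(beta1)/n)^2`` via its log, starting at the grid argmin."""
        i = int(np.argmin(sr.logmags))
        lo = sr.grid[max(i - 1, 0)]
        hi = sr.grid[min(i + 1, sr.grid.size - 1)]

        def neg_log_obj(b):
            return estfun(self.data, self.method, b).logmag

        res = optimize.minimize_scalar(neg_log_obj, bounds=(lo, hi), method="bounded")
        beta1 = float(res.x)
        logmag = float(res.fun)
        if logmag > sr.logmags[i]:  # polishing must not do worse than the grid
            beta1, logmag = float(sr.grid[i]), float(sr.logmags[i])
        obj = math.exp(2.0 * (logmag - math.log(self.data.n)))
        return beta1, obj

    def _sandwich_se(self, beta1: float):
        """Just-identified two-moment sandwich SE at (intercept, beta1).

        Returns None when the moment values or the derivative ("bread")
        matrix are numerically unusable — the applied-analysis situation in
        which software reports an estimate but no confidence interval.
        """
        ds = self.data
        g, x, y = ds.g, ds.x, ds.y.astype(float)
        try:
            b0 = self.nuisance_intercept(beta1)
        except DegenerateDataError:
            return None
        with np.errstate(over="ignore", invalid="ignore"):
            if self.method is MethodKind.MGMM:
                a = y * np.exp(-beta1 * x)
                m = np.column_stack([a - b0, g * (a - b0)])
                bread = np.array(
                    [
                        [-1.0, -np.mean(x * a)],
                        [-np.mean(g), -np.mean(g * x * a)],
                    ]
                )
            else:
                mu = np.exp(b0 + beta1 * x)
                r = y - mu
                m = np.column_stack([r, g * r])
                bread = np.array(
                    [
                        [-np.mean(mu), -np.mean(x * mu)],
                        [-np.mean(g * mu), -np.mean(g * x * mu)],
                    ]
                )
        if not (np.isfinite(m).all() and np.isfinite(bread).all()):
            return None
        if np.linalg.cond(bread) > 1e12:
            return None
        omega = (m.T @ m) / ds.n
        binv = np.linalg.inv(bread)
        v = binv @ omega @ binv.T / ds.n
        if v[1, 1] <= 0 or not np.isfinite(v[1, 1]):
            return None
        return float(math.sqrt(v[1, 1]))


class RiskRatioGMMResults(_ResultsBase):
    """Estimate, uncertainty and identification diagnostics for a GMM fit."""

    def __init__(self, model, beta1, se, scan_result, objective_minimum):
        self.model = model
        self.beta1 = float(beta1)
        self.se = se
        self.scan_result = scan_result
        self.objective_minimum = objective_minimum
        self.nobs = model.data.n

    @property
    def method_label(self) -> str:
        return self.model.method.name

    @property
    def status(self) -> IdentificationStatus:
        return self.scan_result.status

    @property
    def multiplicity_flag(self) -> str:
        return self.status.value

    @property
    def roots(self) -> np.ndarray:
        return self.scan_result.roots

    def summary(self) -> str:
        lines = [
            f"{self.method_label} causal risk ratio estimate (n = {self.nobs})",
            "-" * 58,
            f"identification status : {self.status.value}"
            + (" (degenerate: no events)" if self.scan_result.degenerate else ""),
            f"sign changes on grid  : {self.scan_result.n_sign_changes}",
            f"roots (beta1 scale)   : {np.round(self.roots, 6).tolist()}",
            f"beta1 (log CRR)       : {self.beta1:.6f}",
            f"CRR exp(beta1)        : {self.crr:.6f}",
        ]
        if self.se is not None:
            lo, hi = self.crr_conf_int()
            lines.append(f"SE(beta1)             : {self.se:.6f}")
            lines.append(f"95% CI for CRR        : ({lo:.6f}, {hi:.6f})")
        else:
            lines.append("SE(beta1)             : not available (singular sandwich)")
        if self.objective_minimum is not None:
            lines.append(
                f"objective minimum     : {self.objective_minimum:.6g} "
                "(no root; squared scaled moment)"
            )
        if self.status is IdentificationStatus.MULTIPLE:
            lines.append(
                "warning: multiple roots — the point estimate is not trustworthy; "
                "report the IV-outcome association test instead"
            )
        return "\n".join(lines)


class ParametricIVResults(_ResultsBase):
    """Results of the two-stage or ratio estimator."""

    def __init__(self, method_label, beta1, se, nobs, first_stage, extra=None):
        self.method_label = method_label
        self.beta1 = float(beta1)
        self.se = se
        self.nobs = nobs
        self.first_stage = first_stage
        self.extra = extra or {}
        self.multiplicity_flag = "NOT_CHECKED"

    def summary(self) -> str:
        lo, hi = self.crr_conf_int()
        lines = [
            f"{self.method_label} causal risk ratio estimate (n = {self.nobs})",
            "-" * 58,
            f"first stage R^2       : {self.first_stage.r2:.6f}",
            f"first stage F         : {self.first_stage.f_stat:.3f}",
            f"beta1 (log CRR)       : {self.beta1:.6f}",
            f"CRR exp(beta1)        : {self.crr:.6f}",
            f"SE(beta1)             : {self.se:.6f}",
            f"95% CI for CRR        : ({lo:.6f}, {hi:.6f})",
        ]
        return "\n".join(lines)


class TwoStageRiskRatio:
    """Two-stage parametric estimator: OLS first stage, log-link second stage.

    The second-stage standard error conditions on the first-stage fitted
    values (first-stage uncertainty is not propagated), the common default
    for this comparator; the CI is therefore approximate.
    """

    def __init__(self, data: IVData):
        self.data = data

    def fit(self) -> ParametricIVResults:
        ds = self.data
        fs = _first_stage(ds)
        xhat = fs.fittedvalues
        if np.allclose(xhat, xhat[0]):
            raise DegenerateDataError("first-stage fitted values are constant")
        fit2 = fit_log_binomial(ds.y, np.column_stack([np.ones(ds.n), xhat]))
        return ParametricIVResults(
            method_label="TWO_STAGE",
            beta1=float(fit2.params[1]),
            se=float(fit2.bse[1]),
            nobs=ds.n,
            first_stage=instrument_strength(ds),
            extra={"stage2_iterations": fit2.n_iter},
        )


class RatioIV:
    """Ratio (Wald) estimator: reduced-form slope over first-stage slope.

    The numerator is the slope of the log-link binomial regression of the
    outcome on the instrument, the denominator the OLS slope of exposure on
    instrument; the delta-method variance treats the two stages as
    independent (their sampling covariance is ignored).
    """

    def __init__(self, data: IVData):
        self.data = data

    def fit(self) -> ParametricIVResults:
        ds = self.data
        fs = _first_stage(ds)
        b_x = float(fs.params[1])
        v_x = float(fs.bse[1]) ** 2
        # declare the denominator numerically zero when the instrument
        # explains no exposure variance beyond rounding (R^2 <= 1e-16)
        var_x = float(ds.x.var())
        if var_x == 0.0 or b_x * b_x * float(ds.g.var()) <= 1e-16 * var_x:
            raise DegenerateDataError(
                "first-stage slope is numerically zero (weak instrument)"
            )
        num = fit_log_binomial(ds.y, np.column_stack([np.ones(ds.n), ds.g]))
        b_y = float(num.params[1])
        v_y = float(num.bse[1]) ** 2
        beta1 = b_y / b_x
        var = v_y / b_x**2 + (b_y**2) * v_x / b_x**4
        return ParametricIVResults(
            method_label="RATIO",
            beta1=beta1,
            se=math.sqrt(var),
            nobs=ds.n,
            first_stage=instrument_strength(ds),
        )
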