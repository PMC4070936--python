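"""Identification diagnostic: grid scan, sign-change count, root refinement.

With a weak instrument the GMM/SMM estimating equations for the causal risk
ratio may have no root or several.  The diagnostic evaluates the profiled
estimating function on a wide beta1 grid (default [-50, 50] in steps of 0.1),
counts sign changes, refines each crossing by bisection, and classifies the
dataset as NO_SOLUTION (0 changes), UNIQUE (1) or MULTIPLE (>= 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .data import DegenerateDataError, IVData
from .estfun import MethodKind, estfun, estfun_grid

__all__ = [
    "GridSpec",
    "IdentificationStatus",
    "ScanResult",
    "scan",
    "count_sign_changes",
    "classify_status",
    "refine_root",
    "export_curve",
]

ROOT_TOL = 1e-8


@dataclass(frozen=True)
class GridSpec:
    """Uniform scan grid ``lo, lo+step, ..., hi`` (endpoints included)."""

    lo: float = -50.0
    hi: float = 50.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        if not 0 < self.step <= (self.hi - self.lo) / 10:
            raise ValueError("require 0 < step <= (hi - lo)/10")

    def points(self) -> np.ndarray:
        span = self.hi - self.lo
        m = span / self.step
        if abs(m - round(m)) < 1e-9:
            return np.linspace(self.lo, self.hi, int(round(m)) + 1)
        pts = np.arange(self.lo, self.hi, self.step)
        return np.append(pts, self.hi)


class IdentificationStatus(str, Enum):
    NO_SOLUTION = "NO_SOLUTION"
    UNIQUE = "UNIQUE"
    MULTIPLE = "MULTIPLE"


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one identification scan.

    ``degenerate`` marks an identically-zero estimating function (no events):
    such a scan carries no information and is reported as NO_SOLUTION with
    zero informative sign changes rather than as "a root everywhere".
    """

    grid: np.ndarray
    signs: np.ndarray
    n_sign_changes: int
    roots: np.ndarray
    status: IdentificationStatus
    method: MethodKind
    logmags: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    def plot(self, ax=None, scale: str = "beta1"):
        """Plot sign(f) * log1p(|f|) of the estimating function over the grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.exp(self.grid) if scale == "crr" else self.grid
        ys = self.signs * np.log1p(np.exp(np.minimum(self.logmags, 700.0)))
        ax.plot(xs, ys, lw=1)
        ax.axhline(0.0, color="k", lw=0.5)
        for r in self.roots:
            ax.axvline(math.exp(r) if scale == "crr" else r, color="r", ls=":", lw=0.8)
        ax.set_xlabel("causal risk ratio exp(beta1)" if scale == "crr" else "beta1")
        ax.set_ylabel("signed log(1+|estimating function|)")
        return ax


def count_sign_changes(signs) -> int:
    """Number of sign changes after discarding exact zeros.

    A zero run flanked by opposite signs therefore contributes exactly one
    change (a grid point landing on a root is one crossing, not two or zero).
    """
    s = np.asarray(signs)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] * s[1:] < 0))


def classify_status(n_changes: int) -> IdentificationStatus:
    """0 changes -> NO_SOLUTION, 1 -> UNIQUE, >= 2 -> MULTIPLE."""
    if n_changes < 0:
        raise ValueError("sign-change count cannot be negative")
    if n_changes == 0:
        return IdentificationStatus.NO_SOLUTION
    if n_changes == 1:
        return IdentificationStatus.UNIQUE
    return IdentificationStatus.MULTIPLE


def refine_root(ds: IVData, method, lo: float, hi: float, tol: float = ROOT_TOL) -> float:
    """Bisect an opposite-sign bracket of the estimating function to ``tol``.

    Bisection is used rather than a secant-type method: the scanned functions
    can be extremely flat or wiggly near weak-instrument roots, and bracket
    maintenance is the property that matters.
    """
    method = MethodKind.coerce(method)
    s_lo = estfun(ds, method, lo).sign
    s_hi = estfun(ds, method, hi).sign
    if s_lo == 0 or s_hi == 0 or s_lo == s_hi:
        raise ValueError(
            f"refine_root needs opposite-sign endpoints, got signs ({s_lo}, {s_hi})"
        )
    a, b = float(lo), float(hi)
    while b - a > tol:
        mid = 0.5 * (a + b)
        s_mid = estfun(ds, method, mid).sign
        if s_mid == 0:
            return mid
        if s_mid == s_lo:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def _collect_roots(ds, method, grid, signs) -> list[float]:
    """Refined roots: one per opposite-sign crossing, plus grid-zero touches."""
    roots: list[float] = []
    nz = np.flatnonzero(signs)
    # crossings between consecutive nonzero entries
    for k in range(nz.size - 1):
        i, j = int(nz[k]), int(nz[k + 1])
        if signs[i] * signs[j] >= 0:
            continue
        if j == i + 1:
            roots.append(refine_root(ds, method, grid[i], grid[j]))
        else:
            # the function is exactly zero on the intervening grid points
            roots.append(0.5 * (grid[i + 1] + grid[j - 1]))
    # zero runs NOT flanked by opposite signs (touches / edge runs)
    zero = signs == 0
    if zero.any() and not zero.all():
        boundaries = np.flatnonzero(np.diff(zero.astype(int)) != 0) + 1
        run_edges = np.concatenate(([0], boundaries, [signs.size]))
        for a, b in zip(run_edges[:-1], run_edges[1:]):
            if not zero[a]:
                continue
            left = signs[a - 1] if a > 0 else 0
            right = signs[b] if b < signs.size else 0
            if left != 0 and right != 0 and left * right < 0:
                continue  # already counted as a crossing
            roots.append(0.5 * (grid[a] + grid[b - 1]))
    return sorted(roots)


def scan(ds: IVData, method, grid: GridSpec | None = None) -> ScanResult:
    """Run the identification diagnostic for one dataset and method."""
    method = MethodKind.coerce(method)
    if grid is None:
        grid = GridSpec()
    if ds.g_is_constant:
        raise DegenerateDataError("instrument is constant; scan is undefined")
    pts = grid.points()
    signs, logmags = estfun_grid(ds, method, pts)
    if not signs.any():
        return ScanResult(
            grid=pts,
            signs=signs,
            n_sign_changes=0,
            roots=np.empty(0),
            status=IdentificationStatus.NO_SOLUTION,
            method=method,
            logmags=logmags,
            degenerate=True,
        )
    n_changes = count_sign_changes(signs)
    roots = np.array(_collect_roots(ds, method, pts, signs))
    return ScanResult(
        grid=pts,
        signs=signs,
        n_sign_changes=n_changes,
        roots=roots,
        status=classify_status(n_changes),
        method=method,
        logmags=logmags,
    )


def export_curve(ds: IVData, method, grid: GridSpec | None = None, scale: str = "beta1") -> pd.DataFrame:
    """Tabulate the estimating function over the grid for plotting.

    Columns: ``parameter`` (beta1, or exp(beta1) on the ``crr`` scale),
    ``estfun`` (reconstituted float; ``+-inf`` sentinel where the true
    magnitude exceeds float range) and boolean ``overflowed``.
    """
    if scale not in ("beta1", "crr"):
        raise ValueError("scale must be 'beta1' or 'crr'")
    if grid is None:
        grid = GridSpec()
    pts = grid.points()
    signs, logmags = estfun_grid(ds, MethodKind.coerce(method), pts)
    log_max = math.log(np.finfo(float).max)
    over = (signs != 0) & (logmags > log_max)
    with np.errstate(over="ignore"):
        vals = np.where(signs == 0, 0.0, signs * np.exp(np.minimum(logmags, log_max)))
    vals[over] = np.inf * signs[over]
    param = np.exp(pts) if scale == "crr" else pts
    return pd.DataFrame({"parameter": param, "estfun": vals, "overflowed": over})
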