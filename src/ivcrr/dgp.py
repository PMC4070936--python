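"""Synthetic data generation for the weak-instrument identification study.

The data-generating model is the no-confounding log-linear design used to
study identification failure in IV analyses of binary outcomes:

    g_i ~ Normal(0, rho2)
    x_i ~ Normal(g_i, 1 - rho2)
    y_i ~ Bernoulli( min{ exp(beta0 + beta1 * x_i), 1 } )

so the exposure has unit marginal variance, the squared population
correlation between instrument and exposure is ``rho2``, ``beta1`` is the log
causal risk ratio and ``exp(beta0)`` the outcome risk at x = 0.  At the
defaults ``beta0 = -3, beta1 = 0.2`` the outcome prevalence is about 5% and
the probability truncation at 1 essentially never fires (it needs x >= 15
under a unit-variance normal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import IVData

__all__ = ["DGPConfig", "generate_dataset", "replicate_seed"]


@dataclass(frozen=True)
class DGPConfig:
    """Parameters of the synthetic data-generating model.

    Parameters
    ----------
    n : int
        Number of individuals (>= 2).
    rho2 : float
        Squared instrument-exposure correlation, in [0, 1).  ``rho2 = 0``
        yields an identically-zero (degenerate) instrument.
    beta0 : float
        Log baseline risk at x = 0.  Default -3.
    beta1 : float
        Log causal risk ratio.  Default 0.2.
    seed : int
        Non-negative seed; identical configs give bit-identical datasets.
    """

    n: int
    rho2: float
    beta0: float = -3.0
    beta1: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ValueError(f"n must be an integer >= 2, got {self.n!r}")
        if not 0.0 <= self.rho2 < 1.0:
            raise ValueError(f"rho2 must lie in [0, 1), got {self.rho2!r}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed!r}")
        if math.exp(self.beta0) > 0.5:
            warnings.warn(
                "exp(beta0) > 0.5: the Bernoulli probability will be truncated "
                "at 1 for a substantial share of individuals",
                UserWarning,
                stacklevel=2,
            )


def generate_dataset(config: DGPConfig) -> IVData:
    """Draw one dataset from the data-generating model, deterministically."""
    rng = np.random.default_rng(config.seed)
    g = rng.normal(0.0, math.sqrt(config.rho2), config.n)
    x = g + rng.normal(0.0, math.sqrt(1.0 - config.rho2), config.n)
    p = np.minimum(np.exp(config.beta0 + config.beta1 * x), 1.0)
    y = (rng.random(config.n) < p).astype(np.int8)
    return IVData(g, x, y)


def replicate_seed(master_seed: int, condition_index: int, replicate_index: int) -> int:
    """Derive the per-replicate seed used by the study engine.

    The seed is the first 32-bit word of
    ``SeedSequence(entropy=master_seed, spawn_key=(condition_index,
    replicate_index))``, so any single replicate of any study condition can be
    regenerated in isolation and results are invariant to execution order.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(condition_index), int(replicate_index))
    )
    return int(ss.generate_state(1, np.uint32)[0])
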