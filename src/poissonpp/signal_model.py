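"""Poisson distribution primitives.

The photocount signal model: counts in a bin are a Poisson random variable
with rate λ (expected counts per bin), whose defining property is that the
mean equals the variance.  For large λ the Poisson CDF is well approximated
by a Gaussian with mean λ and variance λ; the approximation error quantifies
when Gaussian-based reasoning (z-scores, normality tests) is safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PoissonSpec", "MomentSet", "poisson_cdf", "normal_approx_error", "poisson_moments"]


@dataclass(frozen=True)
class PoissonSpec:
    """Poisson law with rate ``rate`` = λ > 0 (expected counts per bin)."""

    rate: float

    def __post_init__(self) -> None:
        if not (self.rate > 0) or not math.isfinite(self.rate):
            raise ValueError(f"Poisson rate must be positive and finite, got {self.rate}")


@dataclass(frozen=True)
class MomentSet:
    """First four moments: mean, variance, skewness, excess kurtosis."""

    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float


def poisson_cdf(k: int, spec: PoissonSpec) -> float:
    """Cumulative probability P(X <= k) for X ~ Poisson(rate).

    Evaluated through an overflow-safe routine (regularized incomplete gamma
    under the hood), exact to machine precision for any practical λ.
    """
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    return float(stats.poisson.cdf(int(k), spec.rate))


def normal_approx_error(spec: PoissonSpec) -> float:
    """Maximum absolute error of the Gaussian approximation to the Poisson CDF.

    Returns eps = max_k |F_Poisson(k; λ) − Φ((k + 0.5 − λ)/√λ)|, with the
    half-integer continuity correction.  The scan covers k in
    [max(0, ⌊λ − 10√λ⌋), ⌈λ + 10√λ⌉]; both CDFs are within 1e-12 of their
    limits outside that window, so the max over the window is the global max.
    """
    lam = spec.rate
    sd = math.sqrt(lam)
    lo = max(0, int(math.floor(lam - 10 * sd)))
    hi = int(math.ceil(lam + 10 * sd))
    ks = np.arange(lo, hi + 1)
    exact = stats.poisson.cdf(ks, lam)
    approx = stats.norm.cdf(ks + 0.5, loc=lam, scale=sd)
    return float(np.max(np.abs(exact - approx)))


def poisson_moments(spec: PoissonSpec) -> MomentSet:
    """Closed-form Poisson moments: mean = var = λ, skew = λ^(−1/2), ex. kurt = 1/λ."""
    lam = spec.rate
    return MomentSet(mean=lam, variance=lam, skewness=lam ** -0.5, excess_kurtosis=1.0 / lam)
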