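"""The Poisson pre-processing (PP) transform and baseline detrenders.

For a count series x[n] with time-varying Poisson rate t[n], plain
detrending x[n] − t[n] removes the trend from the mean but not from the
variance (which stays t[n]), so trend information leaks into any
variance-sensitive analysis.  The PP transform instead

1. standardizes by the trend:      s[n] = (x[n] − t[n]) / √t[n],
2. restores a stationary count:    p[n] = ⌊√t′ · s[n] + t′⌋,

with a constant restoration level t′ ≥ |min_n(x[n] − t[n])| so that every
p[n] is a non-negative integer.  The result is wide-sense stationary with
mean ≈ variance ≈ t′ — i.e. Poisson-like again — and lives on the same
integer phase-space lattice as the input.  Stationary integer input with a
constant integer trend t = t′ passes through unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .series import CountSeries, RealSeries
from .trend import TrendEstimate, estimate_trend

__all__ = [
    "PreprocessResult",
    "standardize",
    "select_t_prime",
    "restore",
    "poisson_preprocess",
    "detrend",
    "zscore",
    "TPrimeWarning",
    "RestorationDomainError",
]


class TPrimeWarning(UserWarning):
    """The chosen restoration level is outside its recommended range."""


class RestorationDomainError(ValueError):
    """√t′·s[n] + t′ went negative: t′ violates the lower bound."""


@dataclass(frozen=True)
class PreprocessResult:
    """Bundle of the PP pipeline outputs and the admissible t′ range.

    ``t_prime_lower`` is the hard lower bound |min(x − t)|; ``t_prime_min_snr``
    the soft lower bound from the quantization-noise argument (0 when no
    measured noise level was supplied); ``t_prime_max`` the N/10 rule.
    """

    standardized: RealSeries
    restored: CountSeries
    t_prime: float
    t_prime_lower: float
    t_prime_min_snr: float
    t_prime_max: float
    trend: TrendEstimate

    def summary(self) -> dict:
        return {
            "t_prime": self.t_prime,
            "t_prime_lower": self.t_prime_lower,
            "t_prime_min_snr": self.t_prime_min_snr,
            "t_prime_max": self.t_prime_max,
            "trend_method": self.trend.method,
            "trend_rss": self.trend.rss,
            "n_samples": len(self.restored),
        }


def _check_lengths(x, t: TrendEstimate) -> None:
    if len(x) != len(t):
        raise ValueError(f"length mismatch: series has {len(x)} samples, trend {len(t)}")


def standardize(x: CountSeries, t: TrendEstimate) -> RealSeries:
    """s[n] = (x[n] − t[n]) / √t[n]: zero mean, unit variance at every n."""
    _check_lengths(x, t)
    tv = t.values
    if np.any(tv <= 0):
        raise ValueError("trend values must be positive for standardization")
    s = (x.samples - tv) / np.sqrt(tv)
    return RealSeries(samples=s, bin_size=x.bin_size, label=x.label)


def select_t_prime(x: CountSeries, t: TrendEstimate, *,
                   prefer_min_trend: bool = True,
                   t_prime_min_snr: float = 0.0) -> float:
    """Choose the restoration level t′.

    Default policy: t′ = min_n t[n] when that satisfies the non-negativity
    bound t′ ≥ |min_n(x[n] − t[n])|, otherwise the ceiling of the bound.
    Emits a ``TPrimeWarning`` (never an error) when t′ exceeds the N/10
    sample-size rule or falls below the quantization-SNR minimum.
    """
    _check_lengths(x, t)
    lower = abs(float(np.min(x.samples - t.values)))
    candidate = float(np.min(t.values)) if prefer_min_trend else math.ceil(lower)
    t_prime = candidate if candidate >= lower else float(math.ceil(lower))
    n_over_10 = len(x) / 10.0
    if t_prime > n_over_10:
        warnings.warn(
            f"t'={t_prime:.6g} exceeds the N/10 rule ({n_over_10:.6g}); the restored "
            "phase-space lattice may be too fine for the sample size",
            TPrimeWarning, stacklevel=2)
    if t_prime < t_prime_min_snr:
        warnings.warn(
            f"t'={t_prime:.6g} is below the quantization-SNR minimum "
            f"({t_prime_min_snr:.6g}); quantization noise may dominate",
            TPrimeWarning, stacklevel=2)
    return t_prime


def restore(s: RealSeries, t_prime: float) -> CountSeries:
    """p[n] = ⌊√t′·s[n] + t′⌋ — back to a stationary non-negative count."""
    if not (t_prime > 0):
        raise ValueError("t_prime must be positive")
    raw = math.sqrt(t_prime) * s.samples + t_prime
    bad = np.flatnonzero(raw < 0)
    if bad.size:
        raise RestorationDomainError(
            f"restoration value negative at index {bad[0]} "
            f"({raw[bad[0]]:.6g}); t'={t_prime} violates the lower bound")
    p = np.floor(raw).astype(np.int64)
    return CountSeries(samples=p, bin_size=s.bin_size, label=s.label)


def poisson_preprocess(x: CountSeries, trend_method: str = "robust_smooth",
                       *, t_prime: float | None = None,
                       t_prime_min_snr: float = 0.0,
                       **trend_options) -> PreprocessResult:
    """Full PP pipeline: estimate trend, standardize, choose t′, restore."""
    trend = estimate_trend(x, trend_method, **trend_options)
    s = standardize(x, trend)
    lower = abs(float(np.min(x.samples - trend.values)))
    if t_prime is None:
        t_prime = select_t_prime(x, trend, t_prime_min_snr=t_prime_min_snr)
    elif t_prime < lower:
        raise ValueError(f"t_prime={t_prime} violates the lower bound {lower:.6g}")
    restored = restore(s, t_prime)
    return PreprocessResult(
        standardized=s, restored=restored, t_prime=float(t_prime),
        t_prime_lower=lower, t_prime_min_snr=float(t_prime_min_snr),
        t_prime_max=len(x) / 10.0, trend=trend)


def detrend(x: CountSeries, t: TrendEstimate, dc: float = 0.0) -> RealSeries:
    """x[n] − t[n] + dc: plain detrending (dc=0) or detrending+DC (dc=t′)."""
    _check_lengths(x, t)
    if dc < 0:
        raise ValueError("dc offset must be non-negative")
    return RealSeries(samples=x.samples - t.values + dc,
                      bin_size=x.bin_size, label=x.label)


def zscore(x: CountSeries | RealSeries) -> RealSeries:
    """Global z-score (x − mean)/sd with the sample (N−1) standard deviation."""
    data = np.asarray(x.samples, dtype=float)
    if data.size < 2:
        raise ValueError("z-score needs at least 2 samples")
    sd = data.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined for a constant series")
    return RealSeries(samples=(data - data.mean()) / sd,
                      bin_size=x.bin_size, label=x.label)
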