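"""Evaluation statistics for count signals and their transforms.

Covers the diagnostics used to judge whether a detrending/pre-processing
step restored a stationary Poisson-like signal: the Fano factor
(variance/mean; 1 for Poisson), Hurst exponents by rescaled-range analysis
(R/S) and detrended fluctuation analysis (DFA), a two-sample chi-square
Poissonness test, segment mean/variance analysis, phase-space lattice
occupancy, the quantization signal-to-noise calculus that bounds the
restoration level t′, and the Lilliefors composite-normality test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .series import CountSeries, RealSeries

__all__ = [
    "FanoEstimate", "HurstEstimate", "GofResult", "SegmentSummary",
    "QuantizationReport", "LatticeReport",
    "fano", "hurst_rra", "hurst_dfa", "chi2_poisson_test", "segment_stats",
    "phase_lattice", "quantization_report", "lilliefors_test",
]


def _values(x) -> np.ndarray:
    if isinstance(x, (CountSeries, RealSeries)):
        return np.asarray(x.samples, dtype=float)
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FanoEstimate:
    """Variance-to-mean ratio; 1 for a Poisson process, >1 super-Poissonian."""

    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_signals: int = 1


@dataclass(frozen=True)
class HurstEstimate:
    """Hurst/scaling exponent from a log-log fluctuation fit."""

    value: float
    method: str
    scales: np.ndarray = field(default_factory=lambda: np.array([]))
    log_fluctuations: np.ndarray = field(default_factory=lambda: np.array([]))
    fit_r2: float = float("nan")


@dataclass(frozen=True)
class GofResult:
    statistic: float
    dof: int
    p_value: float
    reject_at_0_05: bool


@dataclass(frozen=True)
class SegmentSummary:
    seg_length: int
    means: np.ndarray
    variances: np.ndarray


@dataclass(frozen=True)
class LatticeReport:
    """Consecutive-sample pairs and the fraction lying on the integer lattice."""

    pairs: np.ndarray  # shape (N-1, 2)
    occupancy: float


@dataclass(frozen=True)
class QuantizationReport:
    """SNR budget of the floor quantization in the restoration step.

    Powers follow the Poisson mean-square value P = t′ + t′²; the uniform
    quantization noise of a unit step has power 1/12, giving
    SNR_Q = 10·log10(12) + 10·log10(t′ + t′²).  ``t_prime_min`` is the
    smallest t′ whose quantization SNR still exceeds the measured SNR;
    ``t_prime_max`` is the N/10 sample-size rule.  The skewness/kurtosis
    biases bound the moment distortion from flooring.
    """

    p_sig: float
    p_noise: float
    snr_db: float
    snr_q_db: float
    t_prime_min: float
    t_prime_max: float
    bias_skewness: float
    bias_kurtosis: float


# ---------------------------------------------------------------------------
# Fano factor
# ---------------------------------------------------------------------------

def fano(signals) -> FanoEstimate:
    """Fano factor F = sample variance / sample mean over the whole series.

    Accepts a single series or an iterable of series; in ensemble mode the
    mean F and a normal-theory 95% interval across signals
    (mean ± 1.96·sd of the per-signal Fano factors) are returned — the
    interval describing where individual signals fall, matching how ensemble
    box plots of the Fano factor are read.
    """
    if isinstance(signals, (CountSeries, RealSeries)) or (
            not isinstance(signals, Iterable)):
        signals = [signals]
    signals = list(signals)
    values = []
    for sig in signals:
        data = _values(sig)
        if data.size < 2:
            raise ValueError("Fano factor needs at least 2 samples")
        mu = data.mean()
        if mu <= 0:
            raise ValueError("Fano factor undefined for non-positive mean")
        values.append(data.var(ddof=1) / mu)
    values = np.asarray(values)
    if values.size == 1:
        return FanoEstimate(value=float(values[0]), n_signals=1)
    mean = float(values.mean())
    spread = float(values.std(ddof=1))
    return FanoEstimate(value=mean, ci_low=mean - 1.96 * spread,
                        ci_high=mean + 1.96 * spread, n_signals=values.size)


# ---------------------------------------------------------------------------
# Hurst exponents
# ---------------------------------------------------------------------------

def hurst_rra(x) -> HurstEstimate:
    """Hurst exponent by rescaled-range (R/S) analysis.

    For each dyadic window size w (8, 16, …, ≤ N/2) the series is cut into
    non-overlapping windows; in each, R is the range of the mean-adjusted
    cumulative sum and S the window standard deviation; R/S is averaged over
    windows and H is the slope of log2⟨R/S⟩ against log2 w.
    """
    data = _values(x)
    n = data.size
    if n < 64:
        raise ValueError("R/S analysis needs at least 64 samples")
    scales, rs_means = [], []
    w = 8
    while w <= n // 2:
        n_win = n // w
        segs = data[: n_win * w].reshape(n_win, w)
        dev = segs - segs.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        s = segs.std(axis=1, ddof=1)
        ok = s > 0
        if np.any(ok):
            scales.append(w)
            rs_means.append(float(np.mean(r[ok] / s[ok])))
        w *= 2
    if len(scales) < 4:
        raise ValueError("insufficient usable scales for R/S analysis")
    logw = np.log2(scales)
    logrs = np.log2(rs_means)
    slope, intercept = np.polyfit(logw, logrs, 1)
    pred = slope * logw + intercept
    ss_res = float(np.sum((logrs - pred) ** 2))
    ss_tot = float(np.sum((logrs - logrs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HurstEstimate(value=float(slope), method="RRA",
                         scales=np.asarray(scales),
                         log_fluctuations=logrs, fit_r2=r2)


def hurst_dfa(x, order: int = 1, n_scales: int = 20) -> HurstEstimate:
    """Scaling exponent by detrended fluctuation analysis.

    The mean-subtracted series is integrated; for ~``n_scales`` log-spaced
    scales s in [10, N/4] an order-``order`` polynomial is fitted in each
    non-overlapping window of the profile and F(s) is the RMS residual;
    the exponent is the slope of log F(s) vs log s.
    """
    data = _values(x)
    n = data.size
    if n < 100:
        raise ValueError("DFA needs at least 100 samples")
    if order < 1:
        raise ValueError("DFA order must be >= 1")
    profile = np.cumsum(data - data.mean())
    raw = np.unique(np.round(np.geomspace(10, n // 4, n_scales)).astype(int))
    raw = raw[raw >= order + 2]
    if raw.size < 4:
        raise ValueError("insufficient scales for DFA")
    log_f, used = [], []
    for s in raw:
        n_win = n // s
        segs = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # vandermonde LS fit batched over windows
        v = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(v, segs.T, rcond=None)
        resid = segs.T - v @ coef
        f = math.sqrt(float(np.mean(resid ** 2)))
        if f > 0:
            used.append(s)
            log_f.append(math.log(f))
    used = np.asarray(used, dtype=float)
    log_s = np.log(used)
    log_f = np.asarray(log_f)
    slope, intercept = np.polyfit(log_s, log_f, 1)
    pred = slope * log_s + intercept
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 - float(np.sum((log_f - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return HurstEstimate(value=float(slope), method="DFA",
                         scales=used.astype(int), log_fluctuations=log_f,
                         fit_r2=r2)


# ---------------------------------------------------------------------------
# Distribution tests
# ---------------------------------------------------------------------------

def _int_histogram(data: np.ndarray, lo: int, hi: int) -> np.ndarray:
    # counts per integer-centered bin [k-0.5, k+0.5); real inputs allowed
    edges = np.arange(lo - 0.5, hi + 1.5)
    h, _ = np.histogram(data, bins=edges)
    # fold everything outside the range into the end bins
    h[0] += int(np.sum(data < lo - 0.5))
    h[-1] += int(np.sum(data >= hi + 0.5))
    return h


def chi2_poisson_test(x, seed: int = 0, reference: np.ndarray | None = None) -> GofResult:
    """Two-sample chi-square test of Poissonness.

    The histogram of ``x`` is compared against the histogram of an equal-size
    synthetic Poisson sample with rate = mean(x), drawn with ``seed``
    (or against ``reference`` when supplied).  Bins are pooled inward from
    both tails until every expected cell count is at least 5; the statistic
    is Σ (O₁−O₂)²/(O₁+O₂) with dof = pooled bins − 1.
    """
    data = _values(x)
    n = data.size
    if n < 100:
        raise ValueError("chi-square Poissonness test needs at least 100 samples")
    lam = data.mean()
    if reference is None:
        if lam <= 0:
            raise ValueError("cannot build a Poisson reference with non-positive mean")
        rng = np.random.default_rng(seed)
        reference = rng.poisson(lam, size=n)
    ref = np.asarray(reference, dtype=float)
    lo = int(math.floor(min(data.min(), ref.min())))
    hi = int(math.ceil(max(data.max(), ref.max())))
    h1 = _int_histogram(data, lo, hi)
    h2 = _int_histogram(ref, lo, hi)
    # pool tail bins until every expected (average) count >= 5
    def pooled(h1, h2):
        exp = (h1 + h2) / 2.0
        i, j = 0, exp.size - 1
        while i < j and exp[i:j + 1].size > 3:
            if exp[i] < 5:
                h1[i + 1] += h1[i]; h2[i + 1] += h2[i]; i += 1
                exp = (h1 + h2) / 2.0
            elif exp[j] < 5:
                h1[j - 1] += h1[j]; h2[j - 1] += h2[j]; j -= 1
                exp = (h1 + h2) / 2.0
            else:
                break
        return h1[i:j + 1], h2[i:j + 1]
    p1, p2 = pooled(h1.astype(float).copy(), h2.astype(float).copy())
    if p1.size < 3:
        raise ValueError("fewer than 3 pooled bins; sample too concentrated")
    tot = p1 + p2
    mask = tot > 0
    statistic = float(np.sum((p1[mask] - p2[mask]) ** 2 / tot[mask]))
    dof = int(mask.sum()) - 1
    p_value = float(stats.chi2.sf(statistic, dof))
    return GofResult(statistic=statistic, dof=dof, p_value=p_value,
                     reject_at_0_05=p_value < 0.05)


def lilliefors_test(x) -> GofResult:
    """Lilliefors composite-normality test (KS with estimated mean/variance)."""
    data = _values(x)
    if data.size < 20:
        raise ValueError("Lilliefors test needs at least 20 samples")
    if data.std() == 0:
        raise ValueError("Lilliefors test undefined for a constant series")
    stat, p = _sm_lilliefors(data, dist="norm")
    p = float(min(max(p, 0.0), 1.0))
    return GofResult(statistic=float(stat), dof=data.size,
                     p_value=p, reject_at_0_05=p < 0.05)


# ---------------------------------------------------------------------------
# Segment / phase-space diagnostics
# ---------------------------------------------------------------------------

def segment_stats(x, seg_length: int) -> SegmentSummary:
    """Per-segment sample mean and variance over ⌊N/seg_length⌋ full segments."""
    data = _values(x)
    if seg_length < 1 or seg_length > data.size:
        raise ValueError("segment length must be in [1, N]")
    n_seg = data.size // seg_length
    segs = data[: n_seg * seg_length].reshape(n_seg, seg_length)
    return SegmentSummary(seg_length=int(seg_length),
                          means=segs.mean(axis=1),
                          variances=segs.var(axis=1, ddof=1))


def phase_lattice(x, tol: float = 1e-9) -> LatticeReport:
    """Pairs (x[n], x[n+1]) and the fraction lying on the unit integer lattice."""
    data = _values(x)
    if data.size < 2:
        raise ValueError("phase space needs at least 2 samples")
    pairs = np.column_stack([data[:-1], data[1:]])
    on_lattice = np.all(np.abs(pairs - np.round(pairs)) <= tol, axis=1)
    return LatticeReport(pairs=pairs, occupancy=float(np.mean(on_lattice)))


# ---------------------------------------------------------------------------
# Quantization / SNR calculus
# ---------------------------------------------------------------------------

def snr_q_db(t_prime: float) -> float:
    """Quantization SNR (dB) of unit-step flooring at restoration level t′."""
    if not (t_prime > 0):
        raise ValueError("t_prime must be positive")
    return 10.0 * math.log10(12.0) + 10.0 * math.log10(t_prime + t_prime ** 2)


def quantization_report(t_prime_sig: float, t_prime_noise: float,
                        n_samples: int) -> QuantizationReport:
    """SNR budget and admissible t′ range for the restoration step.

    ``t_prime_sig`` / ``t_prime_noise`` are the Poisson levels of the signal
    and of the measurement noise (e.g. detector dark count); powers follow
    P = t′ + t′².  ``t_prime_min`` solves SNR_Q(t′) = SNR exactly (quadratic
    in t′); flooring bias requires t′ > 1.
    """
    if not (t_prime_sig > 1):
        raise ValueError("t_prime_sig must exceed 1 (flooring bias undefined below)")
    if not (t_prime_noise > 0):
        raise ValueError("t_prime_noise must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    p_sig = t_prime_sig + t_prime_sig ** 2
    p_noise = t_prime_noise + t_prime_noise ** 2
    snr = 10.0 * math.log10(p_sig / p_noise)
    # smallest t' with SNR_Q(t') >= snr: t'^2 + t' = 10^(snr/10)/12
    c = 10.0 ** (snr / 10.0) / 12.0
    t_min = (-1.0 + math.sqrt(1.0 + 4.0 * c)) / 2.0
    tp = t_prime_sig
    return QuantizationReport(
        p_sig=p_sig, p_noise=p_noise, snr_db=snr, snr_q_db=snr_q_db(tp),
        t_prime_min=t_min, t_prime_max=n_samples / 10.0,
        bias_skewness=1.0 / math.sqrt(tp - 1.0) - 1.0 / math.sqrt(tp),
        bias_kurtosis=1.0 / (tp - 1.0) - 1.0 / tp)
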