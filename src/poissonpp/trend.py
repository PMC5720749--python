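"""Trend (time-varying Poisson rate) estimation.

The slowly varying expected count t[n] = λ[n] of a photocount series is what
the pre-processing standardizes by, so it must follow slow changes of the
signal while ignoring the Poisson fluctuations around them.  Three estimators
are provided:

``gauss2``
    Nonlinear least-squares fit of a sum of two Gaussian bumps over the
    sample index — suited to burst-shaped signals such as the oxidative
    burst of stimulated neutrophils.
``robust_smooth``
    Penalized least squares in the discrete cosine basis with the smoothing
    parameter chosen by generalized cross-validation (GCV) and iterative
    bisquare down-weighting of outliers (the Garcia smoother).
``constant``
    The sample mean, for stationary signals.

All estimators clamp the fitted trend to a small positive floor so that the
standardization s[n] = (x[n] − t[n])/√t[n] and Poisson sampling at rate t[n]
are always defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.fft import dct, idct

from .series import CountSeries

__all__ = ["TrendEstimate", "estimate_trend", "robust_smooth", "TREND_FLOOR"]

# Poisson rate 0 is incompatible with the √t[n] standardization, so fitted
# trends are clamped to this floor.
TREND_FLOOR = 0.5


class TrendConvergenceError(RuntimeError):
    """Raised when a nonlinear trend fit fails after all restarts."""


@dataclass(frozen=True)
class TrendEstimate:
    """A fitted trend t[n] aligned sample-by-sample with its input series.

    ``values`` are strictly positive; ``method`` tags the estimator;
    ``params`` holds the method-specific fitted parameters; ``rss`` is the
    residual sum of squares against the input.
    """

    values: np.ndarray
    method: str
    params: Mapping[str, float] = field(default_factory=dict)
    rss: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("trend values must be a non-empty 1-D sequence")
        if not np.all(arr > 0):
            raise ValueError("trend values must be strictly positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Robust DCT smoother (penalized least squares + GCV + bisquare reweighting)
# ---------------------------------------------------------------------------

def _dct_eigenvalues(n: int) -> np.ndarray:
    # Eigenvalues of the second-difference (discrete Laplacian) operator in
    # the DCT-II basis with reflective boundaries.
    return -2.0 + 2.0 * np.cos(np.arange(n) * np.pi / n)


def _smooth_step(y: np.ndarray, w: np.ndarray, z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    # One fixed-point update of the weighted penalized LS solution.
    return idct(gamma * dct(w * (y - z) + z, norm="ortho"), norm="ortho")


def _gcv_score(log10s: float, y: np.ndarray, w: np.ndarray, z: np.ndarray,
               lam2: np.ndarray, n_valid: float) -> float:
    gamma = 1.0 / (1.0 + (10.0 ** log10s) * lam2)
    z_new = _smooth_step(y, w, z, gamma)
    rss = float(np.sum(w * (y - z_new) ** 2))
    tr_h = float(np.sum(gamma))
    n = y.size
    denom = (1.0 - tr_h / n) ** 2
    return rss / (n_valid * denom) if denom > 0 else np.inf


def _bisquare_weights(r: np.ndarray, h: float) -> np.ndarray:
    mad = np.median(np.abs(r - np.median(r)))
    if mad <= 0:
        return np.ones_like(r)
    u = np.abs(r / (1.4826 * mad * math.sqrt(max(1.0 - h, 1e-12))))
    w = (1.0 - (u / 4.685) ** 2) ** 2
    w[u >= 4.685] = 0.0
    return w


def robust_smooth(y: np.ndarray, robust_iters: int = 3, max_inner: int = 100,
                  tol: float = 1e-5) -> tuple[np.ndarray, float]:
    """Robustly smooth ``y``; returns (smoothed, chosen smoothing parameter).

    Penalized least squares min ||√W(y−z)||² + s·||D z||² solved in the DCT
    basis (reflective boundaries); s minimizes the GCV score over a log grid
    refined by bounded scalar minimization; ``robust_iters`` rounds of
    bisquare reweighting protect the fit against outliers.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("robust_smooth needs at least 10 samples")
    lam2 = _dct_eigenvalues(n) ** 2
    w = np.ones(n)
    z = np.full(n, y.mean())
    s = 1.0
    for it in range(robust_iters + 1):
        n_valid = float(np.sum(w > 0)) or float(n)
        res = optimize.minimize_scalar(
            _gcv_score, bounds=(-8.0, 10.0), args=(y, w, z, lam2, n_valid),
            method="bounded", options={"xatol": 0.05},
        )
        s = 10.0 ** res.x
        gamma = 1.0 / (1.0 + s * lam2)
        # iterate the weighted solution to convergence at fixed s
        for _ in range(max_inner):
            z_new = _smooth_step(y, w, z, gamma)
            delta = np.linalg.norm(z_new - z) / (np.linalg.norm(z_new) + 1e-300)
            z = z_new
            if delta < tol:
                break
        if it < robust_iters:
            # leverage of the equivalent smoother matrix (per-dimension form)
            h0 = math.sqrt(1.0 + 16.0 * s)
            h = math.sqrt(1.0 + h0) / (math.sqrt(2.0) * h0) * 2.0  # in (0, 1]
            w = _bisquare_weights(y - z, min(h, 0.99))
    return z, s


# ---------------------------------------------------------------------------
# Two-Gaussian burst fit
# ---------------------------------------------------------------------------

def _gauss2(n: np.ndarray, a1: float, b1: float, c1: float,
            a2: float, b2: float, c2: float) -> np.ndarray:
    return a1 * np.exp(-(((n - b1) / c1) ** 2)) + a2 * np.exp(-(((n - b2) / c2) ** 2))


def _fit_gauss2(x: np.ndarray, seed: int = 0, restarts: int = 5):
    n_idx = np.arange(1, x.size + 1, dtype=float)
    n = x.size
    # moving-average smoothing for a stable argmax
    win = max(5, n // 100)
    kernel = np.ones(win) / win
    xs = np.convolve(x, kernel, mode="same")
    i1 = int(np.argmax(xs))
    p0 = [max(xs[i1], 1e-3), n_idx[i1], n / 8.0, 0.0, 0.0, 0.0]

    lo = [0.0, -n, 1e-6, 0.0, -n, 1e-6]
    hi = [np.inf, 2.0 * n, 10.0 * n, np.inf, 2.0 * n, 10.0 * n]

    def try_fit(p0_full):
        popt, _ = optimize.curve_fit(_gauss2, n_idx, x, p0=p0_full,
                                     bounds=(lo, hi), maxfev=20000)
        return popt

    rng = np.random.default_rng(seed)
    # second component initialized at the largest residual peak
    resid = xs - _gauss2(n_idx, *p0[:3], 0.0, 1.0, 1.0)
    i2 = int(np.argmax(resid))
    inits = [[p0[0], p0[1], p0[2], max(resid[i2], 1e-3), n_idx[i2], n / 8.0]]
    for _ in range(restarts):
        inits.append([
            xs.max() * rng.uniform(0.2, 1.2), rng.uniform(1, n), n * rng.uniform(0.02, 0.5),
            xs.max() * rng.uniform(0.0, 0.8), rng.uniform(1, n), n * rng.uniform(0.02, 0.5),
        ])
    last_err: Exception | None = None
    best = None
    best_rss = np.inf
    for init in inits:
        try:
            popt = try_fit(init)
        except (RuntimeError, optimize.OptimizeWarning) as err:  # no convergence
            last_err = err
            continue
        rss = float(np.sum((x - _gauss2(n_idx, *popt)) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise TrendConvergenceError(f"two-Gaussian fit failed after restarts: {last_err}")
    return best, best_rss


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def estimate_trend(x: CountSeries, method: str = "robust_smooth",
                   **options) -> TrendEstimate:
    """Estimate the time-varying rate t[n] of a count series.

    ``method`` is one of ``gauss2``, ``robust_smooth``, ``constant``.
    Options: ``seed`` and ``restarts`` for gauss2; ``robust_iters`` for
    robust_smooth.  The returned values are clamped to ``TREND_FLOOR``.
    """
    data = x.samples.astype(float)
    if data.size < 10:
        raise ValueError("trend estimation needs at least 10 samples")
    if method == "constant":
        mu = float(data.mean())
        if mu <= 0:
            raise ValueError("degenerate trend: all-zero series has no positive mean")
        values = np.full(data.size, mu)
        rss = float(np.sum((data - mu) ** 2))
        return TrendEstimate(values=np.maximum(values, TREND_FLOOR),
                             method="constant", params={"mean": mu}, rss=rss)
    if method == "robust_smooth":
        z, s = robust_smooth(data, robust_iters=int(options.get("robust_iters", 3)))
        rss = float(np.sum((data - z) ** 2))
        return TrendEstimate(values=np.maximum(z, TREND_FLOOR),
                             method="robust_smooth", params={"smoothing": s}, rss=rss)
    if method == "gauss2":
        popt, rss = _fit_gauss2(data, seed=int(options.get("seed", 0)),
                                restarts=int(options.get("restarts", 5)))
        n_idx = np.arange(1, data.size + 1, dtype=float)
        values = _gauss2(n_idx, *popt)
        params = dict(zip(["a1", "b1", "c1", "a2", "b2", "c2"], map(float, popt)))
        return TrendEstimate(values=np.maximum(values, TREND_FLOOR),
                             method="gauss2", params=params, rss=rss)
    raise ValueError(f"unknown trend method: {method!r}")
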