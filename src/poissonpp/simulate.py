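"""Seeded synthetic photocount generators.

Model signals emulate the study designs used to validate the pre-processing:

* a linearly increasing rate t[n] = 0.5·n + 10 over N = 1000 bins (the
  canonical nonstationary example),
* a two-Gaussian "oxidative burst" rate resembling stimulated-neutrophil
  chemiluminescence (rising from tens to ~2000 counts/bin over 30000 bins
  of 50 ms),
* constant rates for stationary controls (λ = 500; or the mung-seed-like
  λ = 50 at 1 s bins),
* iid normal draws as the non-Poisson control,
* a bank of n_trends × n_realizations Poisson signals with a per-signal
  seed ledger (the 10 × 100 = 1000-signal evaluation design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .series import CountSeries, RealSeries
from .trend import TrendEstimate

__all__ = [
    "TrendSpec", "ModelBank", "make_trend", "gen_poisson_series",
    "gen_normal_series", "model_bank", "neutrophil_burst_trend",
    "linear_ramp_trend",
]

#: Default two-Gaussian burst parameters (counts/bin over sample index):
#: chosen to resemble a stimulated-neutrophil burst — a baseline of a few
#: tens of counts rising to a ~2200-count peak around a third of the record
#: and decaying with a broad shoulder, over 30000 bins.
BURST_PARAMS = {"a1": 1800.0, "b1": 13000.0, "c1": 7000.0,
                "a2": 700.0, "b2": 21000.0, "c2": 10000.0}


@dataclass(frozen=True)
class TrendSpec:
    """Declarative trend description: kind ∈ {linear, gauss2, constant}."""

    kind: str
    params: Mapping[str, float]
    n_samples: int

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gauss2", "constant"):
            raise ValueError(f"unknown trend kind: {self.kind!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass(frozen=True)
class ModelBank:
    """A seeded bank of model signals with a regeneration ledger.

    ``manifest`` rows are (trend_id, realization_id, seed) so any single
    signal can be regenerated in isolation.
    """

    signals: list
    manifest: list


def make_trend(spec: TrendSpec) -> TrendEstimate:
    """Materialize a trend t[n] over sample index n = 1..N."""
    n = np.arange(1, spec.n_samples + 1, dtype=float)
    p = dict(spec.params)
    if spec.kind == "linear":
        values = p["slope"] * n + p["intercept"]
    elif spec.kind == "constant":
        values = np.full(spec.n_samples, float(p["rate"]))
    else:  # gauss2
        values = (p["a1"] * np.exp(-(((n - p["b1"]) / p["c1"]) ** 2))
                  + p["a2"] * np.exp(-(((n - p["b2"]) / p["c2"]) ** 2)))
    if np.any(values <= 0):
        raise ValueError(f"{spec.kind} trend is non-positive somewhere on 1..{spec.n_samples}")
    return TrendEstimate(values=values, method=spec.kind, params=p)


def linear_ramp_trend(n_samples: int = 1000, slope: float = 0.5,
                      intercept: float = 10.0) -> TrendEstimate:
    """The canonical nonstationary example: t[n] = 0.5·n + 10, n = 1..1000."""
    return make_trend(TrendSpec("linear", {"slope": slope, "intercept": intercept},
                                n_samples))


def neutrophil_burst_trend(n_samples: int = 30000,
                           params: Mapping[str, float] | None = None) -> TrendEstimate:
    """Two-Gaussian burst rate resembling a stimulated-neutrophil signal."""
    return make_trend(TrendSpec("gauss2", params or BURST_PARAMS, n_samples))


def gen_poisson_series(trend: TrendEstimate, seed: int, bin_size: float = 1.0,
                       label: str = "") -> CountSeries:
    """Independent Poisson(t[n]) draw per sample; reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    samples = rng.poisson(trend.values)
    return CountSeries(samples=samples, bin_size=bin_size, label=label)


def gen_normal_series(mean: float, variance: float, n: int, seed: int,
                      bin_size: float = 1.0, label: str = "") -> RealSeries:
    """iid normal draws — the non-Poisson control signal."""
    if not (variance > 0):
        raise ValueError("variance must be positive")
    rng = np.random.default_rng(seed)
    samples = rng.normal(mean, np.sqrt(variance), size=n)
    return RealSeries(samples=samples, bin_size=bin_size, label=label)


def model_bank(trends: Sequence[TrendEstimate], realizations: int,
               base_seed: int, bin_size: float = 1.0) -> ModelBank:
    """Generate len(trends) × realizations Poisson signals with ledgered seeds.

    Per-signal seeds are spawned counter-style from ``base_seed`` through
    ``SeedSequence`` so the streams are statistically independent.
    """
    if len(trends) == 0:
        raise ValueError("trend list must be non-empty")
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(trends) * realizations)
    signals, manifest = [], []
    idx = 0
    for ti, trend in enumerate(trends):
        for ri in range(realizations):
            child_seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
            sig = gen_poisson_series(trend, seed=child_seed, bin_size=bin_size,
                                     label=f"trend{ti}_r{ri}")
            signals.append(sig)
            manifest.append((ti, ri, child_seed))
            idx += 1
    return ModelBank(signals=signals, manifest=manifest)
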