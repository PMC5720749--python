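"""Core series containers.

A photon-counting detector accumulates counts in fixed time bins, so the raw
signal is an ordered sequence of non-negative integers with a bin size in
seconds (``CountSeries``).  Detrended or standardized signals are real-valued
(``RealSeries``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CountSeries", "RealSeries"]


@dataclass(frozen=True)
class CountSeries:
    """Non-negative integer photocounts per time bin.

    Parameters
    ----------
    samples : array-like of int
        Counts per bin; every sample must be a non-negative integer.
    bin_size : float
        Bin duration in seconds (default 1.0).
    label : str
        Free-text identifier carried through the pipeline.
    """

    samples: np.ndarray
    bin_size: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("CountSeries requires a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("CountSeries samples must be finite")
        if np.any(arr < 0):
            raise ValueError("CountSeries samples must be non-negative")
        as_int = arr.astype(np.int64)
        if not np.array_equal(as_int, arr):
            raise ValueError("CountSeries samples must be integers")
        if not (self.bin_size > 0):
            raise ValueError("bin_size must be positive")
        object.__setattr__(self, "samples", as_int)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def values(self) -> np.ndarray:
        return self.samples

    def with_samples(self, samples: np.ndarray) -> "CountSeries":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class RealSeries:
    """Ordered real-valued samples (detrended / standardized signals)."""

    samples: np.ndarray
    bin_size: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("RealSeries requires a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("RealSeries samples must be finite")
        if not (self.bin_size > 0):
            raise ValueError("bin_size must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def values(self) -> np.ndarray:
        return self.samples
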