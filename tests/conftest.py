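import numpy as np
import pytest

import poissonpp as pp


@pytest.fixture(scope="session")
def burst_trend():
    """The two-Gaussian neutrophil-like burst rate, N = 30000."""
    return pp.neutrophil_burst_trend()


@pytest.fixture(scope="session")
def burst_ensemble(burst_trend):
    """30 seeded Poisson realizations of the burst trend, each run through
    the full pre-processing pipeline with robust-smoothing trend estimation.

    Shared by the Fano, Hurst and distribution-preservation checks so the
    (comparatively expensive) robust smoothing runs once per session.
    """
    out = []
    for i in range(30):
        x = pp.gen_poisson_series(burst_trend, seed=10_000 + i)
        res = pp.poisson_preprocess(x, "robust_smooth")
        out.append((x, res))
    return out
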