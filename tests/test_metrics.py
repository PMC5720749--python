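"""Evaluation statistics: Fano, Hurst (R/S, DFA), chi-square, segments,
phase-space lattice, quantization SNR calculus, Lilliefors."""

import math

import numpy as np
import pytest

import poissonpp as pp
from poissonpp.metrics import snr_q_db


def _counts(values, **kw):
    return pp.CountSeries(samples=np.asarray(values, dtype=np.int64), **kw)


# ---------------------------------------------------------------------------
# Fano factor
# ---------------------------------------------------------------------------

def test_fano_of_stationary_poisson_is_near_one():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 500.0}, 3000))
    x = pp.gen_poisson_series(tr, seed=17)
    assert 0.93 < pp.fano(x).value < 1.07


def test_fano_of_constant_series_is_zero():
    assert pp.fano(_counts([7, 7, 7, 7])).value == 0.0


def test_fano_ensemble_interval_brackets_the_mean():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 50.0}, 2000))
    sigs = [pp.gen_poisson_series(tr, seed=100 + i) for i in range(20)]
    est = pp.fano(sigs)
    assert est.n_signals == 20
    assert est.ci_low <= est.value <= est.ci_high
    assert est.ci_low < 1.0 < est.ci_high


def test_fano_converges_to_one_for_long_poisson_series():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 50.0}, 30000))
    devs = [abs(pp.fano(pp.gen_poisson_series(tr, seed=300 + i)).value - 1.0)
            for i in range(20)]
    assert np.mean(np.array(devs) < 0.05) >= 0.95


def test_fano_rejects_zero_mean():
    with pytest.raises(ValueError, match="non-positive mean"):
        pp.fano(_counts([0, 0, 0]))


# ---------------------------------------------------------------------------
# Hurst exponents
# ---------------------------------------------------------------------------

def test_rra_of_iid_poisson_is_near_one_half():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 50.0}, 30000))
    hs = [pp.hurst_rra(pp.gen_poisson_series(tr, seed=400 + i)).value
          for i in range(40)]
    # small-sample R/S bias is upward, hence the asymmetric band
    assert 0.5 <= np.mean(hs) <= 0.65


def test_rra_inflated_by_a_trend_and_restored_by_preprocessing():
    tr = pp.linear_ramp_trend(1000)
    x = pp.gen_poisson_series(tr, seed=8)
    h_raw = pp.hurst_rra(x).value
    res = pp.poisson_preprocess(x, "robust_smooth")
    h_pp = pp.hurst_rra(res.restored).value
    h_det = pp.hurst_rra(pp.detrend(x, res.trend, dc=0.0)).value
    assert h_raw > 0.8          # artifactual persistence from the trend
    assert abs(h_pp - h_det) < 0.1
    assert h_pp < h_raw - 0.2


def test_rra_estimate_metadata():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 50.0}, 4096))
    est = pp.hurst_rra(pp.gen_poisson_series(tr, seed=1))
    assert est.method == "RRA"
    assert np.all(np.diff(est.scales) > 0)
    assert est.fit_r2 > 0.9


def test_rra_needs_enough_samples():
    with pytest.raises(ValueError):
        pp.hurst_rra(_counts(np.arange(32)))


def test_dfa_of_iid_sequence_is_near_one_half():
    rng = np.random.default_rng(0)
    alphas = [pp.hurst_dfa(rng.poisson(50.0, 10000)).value for _ in range(20)]
    assert abs(np.mean(alphas) - 0.5) < 0.05


def test_dfa_of_integrated_white_noise_is_near_three_halves():
    rng = np.random.default_rng(7)
    walk = np.cumsum(rng.normal(size=30000))
    assert pp.hurst_dfa(walk).value == pytest.approx(1.5, abs=0.15)


def test_dfa_insensitive_to_preprocessing_of_stationary_data():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 50.0}, 10000))
    x = pp.gen_poisson_series(tr, seed=19)
    res = pp.poisson_preprocess(x, "constant")
    a_raw = pp.hurst_dfa(x).value
    a_det = pp.hurst_dfa(pp.detrend(x, res.trend, dc=0.0)).value
    a_pp = pp.hurst_dfa(res.restored).value
    assert abs(a_raw - a_det) < 0.03
    assert abs(a_raw - a_pp) < 0.03


def test_dfa_rejects_short_input_and_bad_order():
    with pytest.raises(ValueError):
        pp.hurst_dfa(np.arange(50))
    with pytest.raises(ValueError):
        pp.hurst_dfa(np.arange(1000), order=0)


# ---------------------------------------------------------------------------
# chi-square Poissonness
# ---------------------------------------------------------------------------

def test_chi2_against_identical_reference_is_exact_null():
    rng = np.random.default_rng(3)
    x = rng.poisson(50.0, 1000)
    r = pp.chi2_poisson_test(_counts(x), reference=x.copy())
    assert r.statistic == 0.0
    assert r.p_value == 1.0
    assert not r.reject_at_0_05


@pytest.mark.parametrize("lam", [13.0, 50.0, 500.0])
def test_chi2_type_one_error_is_near_nominal(lam):
    rng = np.random.default_rng(int(lam))
    reps = 400
    rejections = 0
    for _ in range(reps):
        x = rng.poisson(lam, 10000)
        r = pp.chi2_poisson_test(x, seed=int(rng.integers(2 ** 31)))
        rejections += r.reject_at_0_05
    assert 0.03 <= rejections / reps <= 0.07


def test_chi2_needs_enough_samples_and_bins():
    with pytest.raises(ValueError):
        pp.chi2_poisson_test(_counts(np.arange(50)))


# ---------------------------------------------------------------------------
# segments / lattice
# ---------------------------------------------------------------------------

def test_segment_count_and_conservation():
    rng = np.random.default_rng(1)
    data = rng.poisson(50.0, 30000)
    seg = pp.segment_stats(data, 1000)
    assert len(seg.means) == len(seg.variances) == 30
    assert math.fsum(seg.means) * 1000 == pytest.approx(data[:30000].sum(), rel=1e-12)


def test_segment_stats_of_constant_series():
    seg = pp.segment_stats(np.full(100, 3.0), 10)
    assert np.all(seg.variances == 0.0)


def test_segment_stats_rejects_oversized_segment():
    with pytest.raises(ValueError):
        pp.segment_stats(np.arange(10), 11)


def test_lattice_occupancy_discriminates_counts_from_reals():
    tr = pp.make_trend(pp.TrendSpec("constant", {"rate": 500.0}, 3000))
    x = pp.gen_poisson_series(tr, seed=14)
    assert pp.phase_lattice(x).occupancy == 1.0
    d = pp.detrend(x, pp.estimate_trend(x, "constant"), dc=0.0)
    assert pp.phase_lattice(d).occupancy < 0.01
    xn = pp.gen_normal_series(500.0, 500.0, 3000, seed=14)
    assert pp.phase_lattice(xn).occupancy < 0.01
    rep = pp.phase_lattice(x)
    assert rep.pairs.shape == (2999, 2)


# ---------------------------------------------------------------------------
# quantization / SNR
# ---------------------------------------------------------------------------

def test_quantization_report_reference_values():
    rep = pp.quantization_report(50.0, 13.0, 30000)
    assert round(rep.snr_q_db) == 45
    assert rep.bias_skewness == pytest.approx(0.0014, abs=5e-5)
    assert rep.bias_kurtosis == pytest.approx(4e-4, abs=1e-5)
    assert rep.t_prime_max == 3000.0
    assert rep.p_sig == 2550.0


def test_quantization_t_prime_min_matches_grid_search_oracle():
    rep = pp.quantization_report(50.0, 13.0, 10000)
    grid = np.linspace(1e-3, 50.0, 2_000_000)
    snr_grid = 10 * np.log10(12.0) + 10 * np.log10(grid + grid ** 2)
    oracle = grid[np.searchsorted(snr_grid, rep.snr_db)]
    assert rep.t_prime_min == pytest.approx(oracle, abs=1e-4)
    assert snr_q_db(rep.t_prime_min) == pytest.approx(rep.snr_db, abs=1e-9)


def test_snr_q_strictly_increasing_in_t_prime():
    ts = np.linspace(0.5, 5000, 1000)
    vals = [snr_q_db(t) for t in ts]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_quantization_report_rejects_degenerate_levels():
    with pytest.raises(ValueError):
        pp.quantization_report(1.0, 13.0, 100)
    with pytest.raises(ValueError):
        pp.quantization_report(50.0, 0.0, 100)


# ---------------------------------------------------------------------------
# Lilliefors
# ---------------------------------------------------------------------------

def test_lilliefors_type_one_error_is_near_nominal():
    rng = np.random.default_rng(2)
    reps = 300
    rejections = sum(pp.lilliefors_test(rng.normal(size=1000)).reject_at_0_05
                     for _ in range(reps))
    assert 0.02 <= rejections / reps <= 0.08


def test_lilliefors_rejects_uniform_data():
    rng = np.random.default_rng(4)
    assert pp.lilliefors_test(rng.uniform(size=1000)).reject_at_0_05


def test_lilliefors_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        pp.lilliefors_test(np.full(100, 2.0))
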