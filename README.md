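# poissonpp

Detrending and stationarization of photon-count time series that **preserves
the Poisson mean = variance law**.

Photocount signals — chemiluminescence, fluorescence, any photon-counting
record — are non-negative integers whose counts per bin follow a Poisson-like
law, so the variance is tied to the mean. When such a signal carries a slow
nonstationary trend t[n] = λ[n], ordinary detrending x[n] − t[n] (or z-score
normalization) removes the trend from the *mean* only: the variance still
tracks t[n], and variance-sensitive analyses (Fano factor, rescaled-range
Hurst estimation, photocount-distribution tests, phase-space methods) report
artifactual structure. `poissonpp` implements the Poisson pre-processing (PP)
transform that fixes this, together with the trend estimators, the
quantization error calculus, and the evaluation statistics used to validate
it. It is aimed at anyone analysing low-intensity counting signals:
biophotonics, photon-correlation experiments, or any Poisson-rate time series
with a baseline drift.

## The transform

Given a count series x[n] with estimated trend t[n]:

```
s[n] = (x[n] − t[n]) / √t[n]          # standardize: mean 0, variance 1
p[n] = ⌊ √t′ · s[n] + t′ ⌋            # restore a stationary count at level t′
```

with the restoration level t′ chosen so that t′ ≥ |min_n(x[n] − t[n])|
(non-negativity; by default t′ = min_n t[n] when admissible). The output
p[n] is a non-negative integer series with mean ≈ variance ≈ t′ — i.e.
Poisson-like and wide-sense stationary — and it lives on the same unit
integer lattice in the phase space (p[n], p[n+1]) as the raw counts.
Stationary Poisson input with a constant integer trend t = t′ passes through
*unchanged*, sample by sample.

The flooring step is ordinary unit-step quantization, so its noise power is
1/12 and the restored signal's quantization SNR is

```
SNR_Q = 10·log10(12) + 10·log10(t′ + t′²)   [dB]
```

which, with the measured experiment SNR, bounds t′ from below; the sample
size bounds it from above (t′ ≲ N/10). The flooring also biases the skewness
and excess kurtosis by at most 1/√(t′−1) − 1/√t′ and 1/(t′−1) − 1/t′.

Trend estimators: two-Gaussian burst fit (`gauss2`), DCT-penalized robust
smoothing with GCV (`robust_smooth`), and the constant mean (`constant`).
Evaluation statistics: Fano factor (variance/mean; 1 for Poisson), Hurst
exponents by rescaled-range analysis and detrended fluctuation analysis,
a two-sample chi-square Poissonness test, segment mean/variance analysis,
phase-space lattice occupancy, and the Lilliefors normality test.

## Worked example

```python
import poissonpp as pp

# a nonstationary Poisson signal: rate ramps from 10.5 to 510 over 1000 bins
trend = pp.linear_ramp_trend(1000)            # t[n] = 0.5*n + 10
x = pp.gen_poisson_series(trend, seed=1)

print("raw Fano:", round(pp.fano(x).value, 2))
res = pp.poisson_preprocess(x, "robust_smooth")
print("t':", res.t_prime, "bounds:", round(res.t_prime_lower, 1), res.t_prime_max)
print("PP  Fano:", round(pp.fano(res.restored).value, 2))
print("RRA raw:", round(pp.hurst_rra(x).value, 2),
      " RRA after PP:", round(pp.hurst_rra(res.restored).value, 2))
```

prints

```
raw Fano: 81.06
t': 56.0 bounds: 55.9 100.0
PP  Fano: 1.0
RRA raw: 1.1  RRA after PP: 0.54
```

The raw series' Fano factor of 81 and rescaled-range exponent of ~1.1 are
pure trend artifacts — the generating process is Poisson (Fano 1) and
uncorrelated (H ≈ 0.5). After pre-processing both statistics return to their
true values, while plain detrending would have left the growing variance in
place. The chosen restoration level t′ = 56 sits inside its admissible range
(lower bound 55.9 from non-negativity, upper bound N/10 = 100).

A command-line interface mirrors the library:

```
poissonpp simulate --kind linear --params '{"slope":0.5,"intercept":10}' \
    --n-samples 1000 --realizations 10 --seed 1 --out-dir sims/
poissonpp preprocess sims/linear_t0_r0.txt --trend robust --variant pp \
    --out pp.txt --report pp.json
poissonpp evaluate pp.txt --metrics fano,rra,dfa,chi2 --out metrics.csv
poissonpp report metrics.csv
```

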