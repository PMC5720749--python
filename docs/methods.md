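# Methods

## Signal model and assumptions

The input is a discrete-time photocount series x[n], n = 1..N: non-negative
integers per bin, with each sample treated as one realization of a Poisson
variable with slowly varying rate λ[n] = t[n]. Two properties of the Poisson
law drive everything here: mean = variance = λ, and integer support (the
pairs (x[n], x[n+1]) occupy a unit lattice in phase space). For λ ≳ 40 the
Gaussian approximation of the Poisson CDF (mean λ, variance λ, evaluated at
k + 0.5 — the half-integer continuity correction) is accurate to about 0.01
in sup norm; without the correction the error at λ = 40 is about 0.04, so
the corrected form is the one `normal_approx_error` reports.

## The pre-processing transform

Standardization s[n] = (x[n] − t[n])/√t[n] gives zero mean and unit
variance at every instant; restoration p[n] = ⌊√t′·s[n] + t′⌋ rescales to a
constant target rate t′ and floors to integers. The √t′ factor is what makes
Var(p) = mean(p) = t′ (up to quantization) and makes the pair of steps the
exact identity on stationary integer data with a constant integer trend
t = t′: √t′·(x − t′)/√t′ + t′ = x.

Choice of t′ (`select_t_prime`): default t′ = min_n t[n], falling back to
⌈|min_n(x[n] − t[n])|⌉ when the trend minimum violates the non-negativity
bound t′ ≥ |min(x − t)|. Out-of-range values of t′ are warnings, not errors:
t′ > N/10 means the restored lattice is too fine for the sample size to
populate, and t′ below the quantization-SNR minimum means flooring noise
rivals the measurement noise. t′ is kept real-valued (the bound is
real-valued); only the fallback path rounds up, to keep a comfortable margin
above the bound.

Quantization calculus (`quantization_report`): Poisson mean-square power is
P = t′ + t′²; unit-step flooring has noise power 1/12, so
SNR_Q = 10·log10(12) + 10·log10(t′ + t′²). Given a measured noise level
(e.g. a detector dark-count rate, also on the Poisson P = t + t² scale),
the smallest admissible t′ solves SNR_Q(t′) = SNR exactly — a quadratic,
t′ₘᵢₙ = (−1 + √(1 + 4·10^(SNR/10)/12))/2. Flooring biases skewness by at
most 1/√(t′−1) − 1/√t′ and excess kurtosis by 1/(t′−1) − 1/t′, which is why
t′ must exceed 1 and why very small t′ (≈ 10, bias ≈ 2%) should be avoided.

Known, deliberate bias: flooring subtracts ~0.5 from the mean and adds ~1/12
to the variance, so the Fano factor of a pre-processed ensemble sits at
1 + ~0.58/t′ (≈ +0.004 at t′ ≈ 130), systematically. This is intrinsic to
integer restoration, negligible for any practical t′, and the reason the
ensemble Fano interval is reported as a distribution interval
(mean ± 1.96·sd across signals) rather than a standard-error CI: the
scientific claim is "individual signals are consistent with Fano 1".

## Trend estimation

* `constant` — the sample mean; for stationary signals.
* `gauss2` — least-squares fit of a₁·exp(−((n−b₁)/c₁)²) + a₂·exp(−((n−b₂)/c₂)²)
  with a ≥ 0, c > 0 over n = 1..N. Initialization: first component at the
  argmax of a moving-average-smoothed copy with width N/8, second at the
  largest residual peak, plus up to 5 seeded random restarts; the best RSS
  wins. No constant offset term is included.
* `robust_smooth` — penalized least squares in the DCT-II basis (reflective
  boundaries): z = IDCT(Γ·DCT(·)) with Γᵢ = 1/(1 + s·λᵢ²), λᵢ the Laplacian
  eigenvalues. The smoothing parameter s minimizes the GCV score (bounded
  search over log₁₀ s ∈ [−8, 10]); 3 rounds of bisquare reweighting
  (tuning constant 4.685, MAD-scaled residuals, leverage-corrected)
  protect against outliers. Weighted solutions are iterated to a 1e−5
  relative fixed point.

All trends are clamped to a floor of 0.5 counts/bin: a zero rate is
incompatible with the √t standardization and with Poisson regeneration.
The two estimators agree within ~10% RMS on burst-shaped signals, so the
pipeline is not sensitive to this choice; a suitable trend is anything
smooth that follows the slow rate changes only.

## Evaluation statistics

* **Fano factor** — sample variance / sample mean over the whole series
  (no windowing); ensembles report the mean and the ±1.96·sd interval
  across signals.
* **R/S (rescaled range)** — dyadic window sizes 8, 16, …, ≤ N/2,
  non-overlapping windows, R/S averaged per scale, H = slope of
  log₂⟨R/S⟩ vs log₂ w. No small-sample (Anis–Lloyd) correction is applied;
  the known upward bias (iid data read ≈ 0.54 at N = 30000) is accepted and
  reflected in test bands.
* **DFA** — profile = cumulative sum of the mean-subtracted series; ~20
  log-spaced scales in [10, N/4]; order-1 polynomial detrending per
  non-overlapping window; exponent = slope of log F(s) vs log s.
* **Chi-square Poissonness** — a genuine two-sample test: the histogram of
  the signal on integer-centered bins against that of an equal-size seeded
  Poisson sample at the signal's mean rate; tail bins pooled until every
  expected (average) cell count ≥ 5; statistic Σ(O₁−O₂)²/(O₁+O₂),
  dof = pooled bins − 1. Real-valued (detrended) inputs are histogrammed on
  the same integer-centered bins, which is what makes their broadened
  distribution detectable.
* **Segment analysis** — ⌊N/L⌋ full segments of length L (default 1000;
  30 segments at N = 30000), per-segment mean and variance; equality of the
  two within sampling error is the operational stationarity check.
* **Lattice occupancy** — fraction of consecutive-sample pairs within 1e−9
  of the integer lattice; 1.0 for any count series, ≈ 0 for detrended or
  Gaussian data.
* **Lilliefors** — composite normality via statsmodels (table-based
  p-values). Reported as the conventional stationary-Gaussian check on
  high-rate signals; stationarity itself is better judged by the segment
  analysis.

## Synthetic data designs

The generators reproduce the study conditions the transform is validated
under, with fixed seeds throughout (counter-based child seeds from a
`SeedSequence`, ledgered per signal so any one is regenerable):

* linear ramp t[n] = 0.5·n + 10, N = 1000 — the canonical nonstationary
  example;
* constant rates λ = 500 (N = 3000) and the mung-seed-like λ = 50 at 1 s
  bins — stationary controls;
* iid normal (μ = 500, σ² = 500, N = 3000) — the non-Poisson control.
  The matching Poisson case has variance = mean = 500, so the variance-500
  reading (σ = √500) is used;
* a two-Gaussian "oxidative burst" rate over N = 30000 bins with defaults
  a₁ = 1800, b₁ = 13000, c₁ = 7000, a₂ = 700, b₂ = 21000, c₂ = 10000 —
  a baseline of a few tens of counts/bin rising to a ≈ 2200 peak and
  decaying through a shoulder, chosen once to resemble published
  stimulated-neutrophil chemiluminescence records (documented constants,
  not fitted to any dataset);
* the bank design: n_trends × n_realizations signals (the 10 × 100 = 1000
  signal evaluation set).

What the generators do *not* emulate: detector dead time, afterpulsing,
super-Poissonian dark counts, or additive detector noise. Passing tests
therefore demonstrate the transform's behaviour on ideal Poisson input;
on real data the detector-noise admixture raises the restored Fano factor
above 1 (experimental stationary signals read ≈ 1.17 against ≈ 2.02 for
pure detector noise), which model data cannot show.

## Problem sizes and numerical choices

The test suite validates ensemble claims on 30 burst realizations of
N = 30000 (shared across the Fano, Hurst and distribution checks) and 100
seeds for the scalar DFA average; `scripts/acceptance.py` runs the full
100-realization designs. Stochastic assertions use fixed seeds and bands
frozen from independent oracle runs (brute-force CDF summation, grid-search
SNR inversion, type-I error simulation). Degenerate inputs fail loudly:
non-integer or negative counts, all-zero series, constant series for
z-score/Lilliefors, t′ ≤ 1 for the bias formulas, restoration values below
zero (with the offending index named).

## Limitations

* The transform assumes the mean-variance equality; applied to
  super-Poissonian input it does not (and cannot) recover a Poisson law —
  which is useful as an a-posteriori check, not a failure mode.
* Trend estimation error propagates into the restored variance; GCV-chosen
  smoothing absorbs a little genuine noise variance (fractions of a
  percent on the Fano factor at these sample sizes).
* R/S is reported without small-sample bias correction; compare like with
  like.
* The chi-square test draws its reference at the estimated rate, making it
  mildly conservative for small λ (type-I ≈ 4% at λ = 13, N = 10000).
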