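# Methods

This package simulates neural field signals with controlled aperiodic and
periodic structure and compares the measures commonly used to quantify
aperiodic ("1/f") activity. This note documents the models, the parameter
choices that matter, the numerical decisions, and what the simulations do
and do not establish about real recordings.

## Signal model

The working definition of aperiodic activity is a power-law spectrum,
P(f) ∝ 1/f^χ, with χ ≥ 0 the aperiodic exponent (χ = 0 white noise,
1 pink, 2 brown). Neural data additionally show spectral "knees" —
frequencies where the log-log spectrum bends — and oscillations, so three
signal families are simulated:

- **Colored noise** (`sim_ts.sim_powerlaw`): white Gaussian noise whose
  amplitude spectrum is rotated by f^(−χ/2). The rotation is anchored at
  1 Hz (the lower bound of the default fitting range) and the DC bin is
  zeroed; output is z-scored. The rotation is exact, so the expected
  log-log slope over any band is −χ.
- **Synaptic-knee signals** (`sim_ts.sim_synaptic_knee`): a Poisson train
  of post-synaptic events (1000 sources at 2 events/s, collapsed into one
  rate-scaled train) convolved with a causal exponential kernel
  exp(−t/τ_d), instant rise. The kernel's squared transfer function is
  Lorentzian, so the PSD is flat below, and falls as 1/f² above, a knee at
  f_k = 1/(2πτ_d). The convolution is computed at 4× the requested rate
  and decimated: sampling the kernel directly at the output rate aliases
  high-frequency power and measurably flattens the spectral tail below its
  analytic exponent of 2 (we measured ≈1.82 instead of 2 without
  oversampling at 500 Hz, τ_d = 15 ms).
- **Oscillations** (`sim_ts.sim_oscillation`): sinusoidal cycles at a
  center frequency CF. Bursting is per-cycle Bernoulli with probability
  `burst_prob` (phase advances through absent cycles by default; a flag
  resets it). Nonzero bandwidth is implemented by jittering the
  instantaneous frequency with a Gaussian-smoothed noise process
  (smoothing timescale ~1/BW, sd of instantaneous frequency = BW/2),
  because a pure sinusoid has zero spectral width.

**Combined signals** z-score each component and add
sqrt(rel_power) × oscillation to the aperiodic component, so `rel_power`
is the oscillation-to-aperiodic variance ratio and the total variance is
1 + rel_power.

Batch generators derive one seed per signal from the master seed by
counter, so any subset of a sweep is independently reproducible.

Power spectra can also be simulated directly (`sim_psd`): log10 P(f) =
offset − log10(knee + f^χ) + Σ Gaussian peaks + white log-power noise
(default sd 0.005). Peak bandwidth is 2× the Gaussian sd throughout —
stated explicitly because a silent factor-of-two drift here is a classic
failure mode. Peak center frequencies are drawn from 3–34 Hz; the draw
accepts an arbitrary probability table and defaults to uniform (the
empirically derived occurrence table this emulates is not shipped).

## Time-domain measures

All measures are implemented from their defining formulas with these
defaults (30 s segments assumed):

| measure | settings (default) |
|---|---|
| autocorrelation | max_lag 250 samples, step 1, biased (1/n) estimator |
| AC decay time | max_lag 1500 samples, step 2, level 0.5 |
| Hurst (R/S) | 10 log-spaced scales, 0.1–2.0 s, per-window mean detrend |
| DFA | 10 log-spaced scales, 0.1–2.0 s, order-1 detrend, non-overlapping windows |
| Higuchi FD | kmax 10 |
| Katz / Petrosian FD | — |
| Hjorth | activity = var, mobility = sd-ratio of derivative, complexity = mobility ratio |
| Lempel-Ziv | median binarization, LZ76 parsing, unnormalized |
| approximate / sample entropy | order m = 2, tolerance r = 0.2 × signal sd |
| permutation entropy | order 3, delay 1, stable (temporal) tie-break |

Notable numerical decisions:

- **AC decay time** interpolates the 0.5-crossing linearly between the two
  bracketing lags. Without interpolation every signal whose
  autocorrelation collapses within the first lag step returns the same
  quantized value (~30% of low-exponent signals in the comparison sets),
  an artifact of the lag grid. If the autocorrelation never reaches the
  level, the record is returned censored at max_lag.
- **Entropy tolerance** defaults to 0.2 × sd, making sample entropy
  invariant to affine rescaling of the signal; the resolved r is recorded
  in the result's settings. A sample-entropy computation with zero
  template matches is censored rather than returning ±inf.
- **Degenerate inputs** (constant signals) raise a typed
  `DegenerateInputError` instead of silently returning NaN.
- The O(n²) entropy kernels are compiled with numba; a 30 s, 500 Hz
  signal's sample entropy runs in ~0.3 s.

Known estimator limits worth keeping in mind: rescaled range saturates
toward H ≈ 1 once the input is nonstationary (χ ≳ 2), and the AC decay
crossing sits on an increasingly flat slope as χ grows, so both measures
lose rank precision at high exponents on 30 s signals. This bounds how
concordant any measure pair involving them can appear (see Limitations).

## Frequency-domain measures

Spectra are estimated with Welch's method (2 s Hann segments, 50% overlap;
resolution 0.5 Hz, sufficient for a 1 Hz lower fit bound). Exponent
estimators:

- **Line fits** of log10 P vs log10 f over 1–50 Hz: OLS, Huber robust
  regression (statsmodels RLM), RANSAC (scikit-learn; inlier threshold =
  2 × 1.4826 × MAD of first-pass OLS residuals, 100 trials, seeded), and a
  nonlinear least-squares fit of the same power-law form in semi-log space
  (EXP). Each supports excluding a fixed alpha band (7–14 Hz).
- **Spectral parameterization** (`specparam_fit`): robust initial
  aperiodic fit (fit, keep only bins within the 2.5th percentile of the
  positive residuals, refit); iterative peak extraction from the flattened
  spectrum (stop at max_n_peaks, or when the next maximum is below
  max(2 sd, min_peak_height)); joint multi-Gaussian refit; final aperiodic
  refit on the peak-subtracted spectrum; R² in log space. Fixed mode fits
  offset − χ log10 f; knee mode offset − log10(k + f^χ), with knee
  frequency k^(1/χ). Defaults: max_n_peaks 8, peak width 1–8 Hz, threshold
  2 sd, min height 0.05 (fixed, 1–50 Hz); knee fits use 1–100 Hz,
  max_n_peaks 12, min height 0.1. Optimizer failures return a flagged
  model, never an exception.
- **IRASA** (`irasa_decompose`): for each h in 1.1–1.95 (step 0.05) the
  signal is resampled by h and 1/h (rational polyphase); both spectra are
  computed with the original sampling rate deliberately left in place,
  which displaces periodic peaks to h±1-multiples of their frequency while
  leaving scale-free structure invariant — and lands both members of the
  pair on the original frequency grid exactly, so no interpolation is
  needed. The geometric mean per pair, median-reduced across the h-set, is
  the aperiodic spectrum; the residual against the original PSD is the
  periodic component. An exponent is obtained by fitting the isolated
  aperiodic spectrum (`fit_aperiodic`), conventionally in fixed (line)
  mode.

On pure synaptic-knee signals we find IRASA followed by an *equivalent
knee-model fit* is not worse than knee-mode parameterization (median |χ
error| ≈ 0.03 vs 0.06, n = 20); the much-cited failure of IRASA on knee
data appears when its output is consumed the standard way, as a log-log
line fit (median |χ error| ≈ 0.55). The knee-divergence comparison in the
acceptance suite therefore pits knee-mode parameterization against
IRASA + line fit.

## Analytic relations

For colored noise, DFA's α relates to χ as α = (χ + 1)/2 under the
convention that χ is the *negated* log-log slope (χ ≥ 0); fractal
dimension satisfies FD = 3 − α and D = (5 − χ)/2 (valid in the fBm regime,
χ ∈ [1, 3]). A sign variant α = (−χ + 1)/2 circulates in the literature
(it identifies χ with the slope itself); both conventions are exposed
(`theory.expected_value(..., convention=...)`) because they agree only at
χ = 0 — simulated DFA on brown noise gives α ≈ 1.5, matching the standard
form and not the printed variant's −0.5.

## Comparison harness and statistics

`evaluate.run_sweep` applies a measure battery to labeled signals and
returns a tidy table (ground truth + one column per measure + censoring
flags; failures are flagged, never dropped). Statistics follow standard
practice: Spearman correlations with pairwise (not listwise) exclusion;
two-sample t-tests and pooled-sd Cohen's d on absolute errors;
case-resampling percentile bootstrap (default 5000 resamples, 95% CI,
two-sided empirical p) for correlation CIs and correlation-difference
tests; semi-partial correlations computed on ranks, removing the control
from the measure only. No multiple-testing correction is applied — results
are reported per pair.

### The comparison protocol

The headline experiment simulates a mixed set — default 250 aperiodic-only
signals (χ uniform on {0, 0.1, …, 2.5}) and 175 combined signals (CF
uniform on 5–35 Hz, rel_power uniform on {0.1, …, 1.0}), 30 s each — and
computes the featured battery: AC decay time, Hurst, DFA, Higuchi, Katz,
Hjorth complexity, Lempel-Ziv, sample entropy, permutation entropy, and
the parameterized spectral exponent.

The protocol samples at **500 Hz**. This choice matters: several measures
have sample-denominated settings, and at 250 Hz Higuchi's kmax = 10
decimation interacts with near-Nyquist oscillations badly enough to invert
its oscillation response across the CF range (a pure 35 Hz sinusoid at
250 Hz has Higuchi D ≈ 2.15; at 500 Hz, ≈ 1.4), which flips correlation
signs between the aperiodic-only and combined matrices. At 500 Hz the
oscillation response of every measure is direction-consistent. The AC
decay window is held fixed in *time* (6 s) across rates.

Problem sizes throughout (425-signal comparison sets, 100 spectra for the
fit comparison, 20 knee signals, 200 × 1000-resample coverage runs) are
the package's desk-scale defaults; `--scale full` in the reproduction CLI
restores the larger originals (e.g. 1000-signal comparison set).

## What the simulations do and do not show

The generators emulate the statistical structure these measures respond
to: exact power-law scaling, Lorentzian knees, and stationary sinusoidal
(optionally bursty) oscillations. They do not emulate nonstationary
exponent drift, non-sinusoidal waveform shape, multichannel covariance,
artifacts, or line noise. Passing tests therefore establish correctness of
the measures and the relative behavior of methods under controlled
conditions — not performance on any particular empirical recording.

Two honest limits of the comparison, measured at these problem sizes:

- The weakest aperiodic-only pair (AC decay × Hurst) plateaus near
  |r| ≈ 0.90 rather than ≈ 0.97, because both estimators lose rank
  precision at high exponents on 30 s signals (R/S saturation; flat-slope
  crossing noise). Longer signals would be required to push this pair
  higher.
- Higuchi's oscillation sensitivity keeps its correlation with oscillation
  power around 0.25–0.30 on combined rows, above the ~0.18 ceiling that
  holds for the other measures.
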