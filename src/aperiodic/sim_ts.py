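"""Simulation of neural field time series with controlled structure.

Aperiodic activity is simulated either as colored noise — white noise whose
amplitude spectrum is rotated to a target 1/f^chi exponent — or with a
physiologically inspired model that convolves a Poisson train of synaptic
events with an exponential-decay kernel, producing a Lorentzian-like
spectrum with a knee near 1/(2*pi*tau_d). Periodic activity is a sinusoidal
oscillation, optionally bursty (each cycle independently present with some
probability) and optionally broadened in bandwidth by slow jitter of the
instantaneous frequency. Combined signals sum a unit-variance aperiodic
component with a scaled unit-variance periodic component, so the oscillation
`rel_power` is the variance ratio between the two.

Batch generators produce labeled parameter sweeps and mixed comparison sets,
with one derived seed per signal so any subset is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .core import AperiodicParams, PeriodicParams, SimSpec, TimeSeries
from .exceptions import InvalidArgumentError

__all__ = [
    "sim_powerlaw",
    "sim_synaptic_knee",
    "sim_oscillation",
    "combine_signals",
    "simulate_from_spec",
    "make_param_sweep",
    "make_comparison_set",
    "EXPONENT_GRID",
    "TAU_GRID",
    "FREQ_GRID",
    "POWER_GRID",
    "BANDWIDTH_GRID",
    "BURST_GRID",
]

# Default sweep grids: exponent 0-3 by 0.5; synaptic decay times (s); CF 5-35
# by 1 Hz; relative power 0-2 by 0.1; bandwidth 0.5-3 by 0.5 Hz; burst
# probability 0.2-0.8 by 0.1.
EXPONENT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 3.01, 0.5), 2))
TAU_GRID: tuple[float, ...] = (0.005, 0.015, 0.030, 0.050, 0.075)
FREQ_GRID: tuple[float, ...] = tuple(float(f) for f in range(5, 36))
POWER_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 2.01, 0.1), 2))
BANDWIDTH_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.5, 3.01, 0.5), 2))
BURST_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.2, 0.81, 0.1), 2))

# Poisson-event model constants: 1000 independent sources firing at
# 2 events/s, collapsed into one rate-scaled train.
_N_SOURCES = 1000
_SOURCE_RATE_HZ = 2.0

# Amplitude rotation anchor for the colored-noise simulation (Hz).
_ROTATION_ANCHOR_HZ = 1.0


def _check_sim_args(n_samples: int, fs: float) -> None:
    if not n_samples > 0:
        raise InvalidArgumentError(f"n_samples must be > 0, got {n_samples}")
    if not fs > 0:
        raise InvalidArgumentError(f"fs must be > 0, got {fs}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidArgumentError("cannot normalize a constant signal")
    return (x - x.mean()) / sd


def sim_powerlaw(n_samples: int, fs: float, exponent: float, seed: int) -> TimeSeries:
    """Simulate colored noise with power-law spectrum 1/f^exponent.

    White Gaussian noise is generated, its amplitude spectrum is rotated
    about 1 Hz by f^(-exponent/2) (DC bin zeroed), and the result is
    transformed back to the time domain and scaled to zero mean, unit
    variance. The log-log spectral slope over 1-50 Hz then approximates
    -exponent.
    """
    _check_sim_args(n_samples, fs)
    if n_samples < 16:
        raise InvalidArgumentError(f"n_samples must be >= 16, got {n_samples}")
    if exponent < 0:
        raise InvalidArgumentError(f"exponent must be >= 0, got {exponent}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        return TimeSeries(_zscore(white), fs)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = (freqs[nonzero] / _ROTATION_ANCHOR_HZ) ** (-exponent / 2.0)
    rotated = np.fft.irfft(spectrum * scale, n=n_samples)
    return TimeSeries(_zscore(rotated), fs)


def sim_synaptic_knee(n_samples: int, fs: float, tau_d: float, seed: int) -> TimeSeries:
    """Simulate aperiodic activity with a spectral knee from synaptic currents.

    A Poisson train of post-synaptic events (1000 sources at 2 events/s,
    collapsed to one rate-scaled train) is convolved with a causal
    single-exponential decay kernel of time constant ``tau_d`` (instant
    rise). The squared transfer function of the kernel is Lorentzian, so the
    PSD is flat at low frequency, bends near 1/(2*pi*tau_d), and falls with
    exponent 2 above the knee.
    """
    _check_sim_args(n_samples, fs)
    if not tau_d > 0:
        raise InvalidArgumentError(f"tau_d must be > 0, got {tau_d}")
    rng = np.random.default_rng(seed)
    # simulate oversampled, then decimate: sampling the exponential kernel
    # directly at fs aliases high-frequency power and flattens the spectral
    # tail below its analytic exponent of 2
    oversample = 4
    fs_int = fs * oversample
    n_int = n_samples * oversample
    rate_per_sample = _N_SOURCES * _SOURCE_RATE_HZ / fs_int
    kernel_len = max(int(np.ceil(7.0 * tau_d * fs_int)), 2)
    # pad the event train so the convolution transient can be trimmed
    events = rng.poisson(rate_per_sample, n_int + kernel_len).astype(float)
    t_kernel = np.arange(kernel_len) / fs_int
    kernel = np.exp(-t_kernel / tau_d)
    sig = np.convolve(events, kernel, mode="full")[kernel_len : kernel_len + n_int]
    sig = sp_signal.resample_poly(sig, 1, oversample)[:n_samples]
    return TimeSeries(_zscore(sig), fs)


def sim_oscillation(
    n_samples: int,
    fs: float,
    periodic: PeriodicParams,
    seed: int,
    phase_continuous: bool = True,
) -> TimeSeries:
    """Simulate a (possibly bursty, possibly broadband) oscillation.

    With ``burst_prob`` = 1 the output is a continuous sinusoid at the
    center frequency; with ``burst_prob`` < 1 each cycle is independently
    present with that probability and zeroed otherwise. A nonzero
    ``bandwidth`` broadens the spectral peak by jittering the instantaneous
    frequency with a smoothed random walk whose spread maps to the target
    bandwidth (sd of instantaneous frequency = bandwidth / 2).

    ``phase_continuous`` controls whether phase keeps advancing through
    absent cycles (default) or resets at the start of each present cycle.
    """
    _check_sim_args(n_samples, fs)
    if periodic.freq >= fs / 2.0:
        raise InvalidArgumentError(
            f"freq {periodic.freq} must be below Nyquist ({fs / 2.0})"
        )
    rng = np.random.default_rng(seed)

    if periodic.bandwidth > 0:
        jitter = rng.standard_normal(n_samples)
        # smooth on a timescale ~ 1/bandwidth so the jitter drifts slowly
        sigma = max(fs / (4.0 * periodic.bandwidth), 1.0)
        jitter = gaussian_filter1d(jitter, sigma, mode="reflect")
        jitter_sd = jitter.std()
        if jitter_sd > 0:
            jitter = jitter / jitter_sd * (periodic.bandwidth / 2.0)
        inst_freq = np.clip(periodic.freq + jitter, 0.1, fs / 2.0 - 1e-9)
    else:
        inst_freq = np.full(n_samples, periodic.freq)

    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
    cycle_idx = np.floor(phase / (2.0 * np.pi)).astype(int)
    n_cycles = cycle_idx[-1] + 1
    present = rng.random(n_cycles) < periodic.burst_prob

    if phase_continuous:
        sig = np.sin(phase) * present[cycle_idx]
    else:
        sig = np.zeros(n_samples)
        for c in np.flatnonzero(present):
            idx = np.flatnonzero(cycle_idx == c)
            local = phase[idx] - phase[idx[0]]
            sig[idx] = np.sin(local)

    if sig.std() > 0:
        sig = sig - sig.mean()
    return TimeSeries(sig, fs)


def combine_signals(
    aperiodic_ts: TimeSeries, periodic_ts: TimeSeries, rel_power: float
) -> TimeSeries:
    """Additively combine aperiodic and periodic components.

    Both components are scaled to zero mean, unit variance; the periodic
    one is then weighted by sqrt(rel_power), so ``rel_power`` is the variance
    of the oscillation relative to the aperiodic component. ``rel_power`` = 0
    (or an all-zero periodic component, e.g. burst probability 0) returns
    the normalized aperiodic signal exactly.
    """
    if aperiodic_ts.n_samples != periodic_ts.n_samples:
        raise InvalidArgumentError(
            f"length mismatch: {aperiodic_ts.n_samples} vs {periodic_ts.n_samples}"
        )
    if aperiodic_ts.fs != periodic_ts.fs:
        raise InvalidArgumentError(
            f"fs mismatch: {aperiodic_ts.fs} vs {periodic_ts.fs}"
        )
    if rel_power < 0:
        raise InvalidArgumentError(f"rel_power must be >= 0, got {rel_power}")
    ap = _zscore(aperiodic_ts.samples)
    if rel_power == 0 or periodic_ts.samples.std() == 0:
        return TimeSeries(ap, aperiodic_ts.fs)
    per = _zscore(periodic_ts.samples)
    return TimeSeries(ap + np.sqrt(rel_power) * per, aperiodic_ts.fs)


def _derived_seed(base_seed: int, counter: int) -> int:
    """Counter-derived per-signal seed; stable, independent of batch size."""
    ss = np.random.SeedSequence(entropy=(int(base_seed), int(counter)))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_from_spec(spec: SimSpec) -> TimeSeries:
    """Simulate the signal a :class:`SimSpec` describes.

    The aperiodic component is the synaptic-knee model when ``tau_d`` is
    set, otherwise rotated colored noise at the specified exponent. A
    periodic component, if present with nonzero relative power, is simulated
    and combined additively. The two components use seeds derived from
    ``spec.seed`` so the whole signal is reproducible.
    """
    seed_ap = _derived_seed(spec.seed, 0)
    if spec.aperiodic.tau_d is not None:
        ap = sim_synaptic_knee(spec.n_samples, spec.fs, spec.aperiodic.tau_d, seed_ap)
    else:
        ap = sim_powerlaw(spec.n_samples, spec.fs, spec.aperiodic.exponent, seed_ap)
    if spec.periodic is None or spec.periodic.rel_power == 0:
        return TimeSeries(_zscore(ap.samples), spec.fs)
    per = sim_oscillation(spec.n_samples, spec.fs, spec.periodic, _derived_seed(spec.seed, 1))
    return combine_signals(ap, per, spec.periodic.rel_power)


_SWEEPABLE = ("exponent", "tau_d", "freq", "rel_power", "bandwidth", "burst_prob")


def _spec_with(base: SimSpec, name: str, value: float, seed: int) -> SimSpec:
    if name in ("exponent", "tau_d"):
        aperiodic = AperiodicParams(
            offset=base.aperiodic.offset,
            exponent=value if name == "exponent" else base.aperiodic.exponent,
            knee=base.aperiodic.knee,
            tau_d=value if name == "tau_d" else None,
        )
        return base.with_(aperiodic=aperiodic, seed=seed)
    periodic = replace(base.periodic or PeriodicParams(freq=10.0), **{name: value})
    return base.with_(periodic=periodic, seed=seed)


def make_param_sweep(
    varying: str,
    grid: Sequence[float],
    n_per_value: int,
    base: SimSpec,
) -> list[tuple[SimSpec, TimeSeries]]:
    """Simulate ``len(grid) * n_per_value`` signals varying one parameter.

    Each output signal is labeled with its full :class:`SimSpec` (ground
    truth + derived seed); the collection is fully reproducible from
    ``base.seed``.
    """
    if varying not in _SWEEPABLE:
        raise InvalidArgumentError(
            f"unknown sweep parameter {varying!r}; expected one of {_SWEEPABLE}"
        )
    if n_per_value < 1:
        raise InvalidArgumentError(f"n_per_value must be >= 1, got {n_per_value}")
    out: list[tuple[SimSpec, TimeSeries]] = []
    counter = 0
    for value in grid:
        for _ in range(n_per_value):
            spec = _spec_with(base, varying, float(value), _derived_seed(base.seed, counter))
            out.append((spec, simulate_from_spec(spec)))
            counter += 1
    return out


def make_comparison_set(
    n_total: int,
    frac_aperiodic: float = 0.3,
    seed: int = 0,
    duration: float = 30.0,
    fs: float = 250.0,
) -> list[tuple[SimSpec, TimeSeries]]:
    """Simulate a mixed set of aperiodic-only and combined signals.

    ``frac_aperiodic`` of the signals are pure colored noise with exponent
    drawn from {0, 0.1, ..., 2.5}; the rest add an oscillation with center
    frequency drawn from {5, 6, ..., 35} Hz and relative power from
    {0.1, ..., 1.0}. Every SimSpec records its ground truth.
    """
    if n_total <= 0:
        raise InvalidArgumentError(f"n_total must be > 0, got {n_total}")
    if not 0 <= frac_aperiodic <= 1:
        raise InvalidArgumentError(
            f"frac_aperiodic must be in [0, 1], got {frac_aperiodic}"
        )
    rng = np.random.default_rng(seed)
    n_aperiodic = int(round(frac_aperiodic * n_total))
    exponents = np.round(np.arange(0.0, 2.51, 0.1), 2)
    cfs = np.arange(5, 36, dtype=float)
    powers = np.round(np.arange(0.1, 1.01, 0.1), 2)

    out: list[tuple[SimSpec, TimeSeries]] = []
    for i in range(n_total):
        exponent = float(rng.choice(exponents))
        aperiodic = AperiodicParams(exponent=exponent)
        if i < n_aperiodic:
            periodic = None
        else:
            periodic = PeriodicParams(
                freq=float(rng.choice(cfs)),
                rel_power=float(rng.choice(powers)),
            )
        spec = SimSpec(
            aperiodic=aperiodic,
            periodic=periodic,
            duration=duration,
            fs=fs,
            seed=_derived_seed(seed, i),
        )
        out.append((spec, simulate_from_spec(spec)))
    return out
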