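"""Direct simulation of neural power spectra.

Spectra are built in log10-power space as an aperiodic component —
``offset - log10(knee + f^exponent)``, reducing to a pure power law when the
knee is 0 — plus Gaussian peaks (height in log10 units, bandwidth = 2 sd)
plus white measurement noise, then exponentiated back to linear power. This
is the standard parametric form used to test spectral-fitting methods
against known ground truth.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import AperiodicParams, PeakParams, PowerSpectrum
from .exceptions import InvalidArgumentError

__all__ = [
    "aperiodic_log_power",
    "gaussian_log_power",
    "sim_power_spectrum",
    "sample_peak_cf",
    "CF_RANGE",
    "PEAK_PW_GRID",
    "PEAK_BW_GRID",
    "PSD_EXPONENT_GRID",
    "DEFAULT_NOISE_SD",
]

# Grids used by the simulated-fit experiments: peak heights, bandwidths (Hz),
# aperiodic exponents, and the integer CF range peaks are drawn from.
PEAK_PW_GRID: tuple[float, ...] = (0.15, 0.25, 0.5, 1.0, 1.5)
PEAK_BW_GRID: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
PSD_EXPONENT_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
CF_RANGE: tuple[int, int] = (3, 34)
DEFAULT_NOISE_SD: float = 0.005


def aperiodic_log_power(freqs: np.ndarray, params: AperiodicParams) -> np.ndarray:
    """log10 power of the aperiodic component at ``freqs``.

    ``offset - log10(knee + f**exponent)``; knee = 0 gives the pure
    power-law ("fixed") form ``offset - exponent * log10(f)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    return params.offset - np.log10(params.knee + freqs**params.exponent)


def gaussian_log_power(freqs: np.ndarray, peak: PeakParams) -> np.ndarray:
    """log10-power contribution of one Gaussian peak at ``freqs``."""
    freqs = np.asarray(freqs, dtype=float)
    return peak.pw * np.exp(-((freqs - peak.cf) ** 2) / (2.0 * peak.sd**2))


def sim_power_spectrum(
    freq_range: tuple[float, float],
    freq_res: float,
    aperiodic: AperiodicParams,
    peaks: Sequence[PeakParams] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PowerSpectrum:
    """Simulate a power spectrum with known aperiodic and periodic structure.

    log10(power) = aperiodic form + sum of Gaussian peaks + white noise of
    standard deviation ``noise_sd`` (log10 units). Frequencies run from
    ``freq_range[0]`` to ``freq_range[1]`` inclusive in steps of
    ``freq_res``.
    """
    lo, hi = freq_range
    if not (0 < lo < hi):
        raise InvalidArgumentError(f"freq_range must satisfy 0 < lo < hi, got {freq_range}")
    if not freq_res > 0:
        raise InvalidArgumentError(f"freq_res must be > 0, got {freq_res}")
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    freqs = np.arange(lo, hi + freq_res / 2.0, freq_res)
    for peak in peaks:
        if not (lo <= peak.cf <= hi):
            raise InvalidArgumentError(
                f"peak cf {peak.cf} outside freq_range {freq_range}"
            )
    log_powers = aperiodic_log_power(freqs, aperiodic)
    for peak in peaks:
        log_powers = log_powers + gaussian_log_power(freqs, peak)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_powers = log_powers + rng.normal(0.0, noise_sd, freqs.size)
    return PowerSpectrum(freqs, 10.0**log_powers)


def sample_peak_cf(
    prob_table: Sequence[float] | None = None, seed: int | np.random.Generator = 0
) -> int:
    """Draw a peak center frequency from 3-34 Hz (1-Hz steps).

    ``prob_table`` gives per-frequency sampling weights over the 32 integer
    frequencies 3..34 and is normalized internally; by default the draw is
    uniform. (The empirical MEG-derived occurrence table this emulates is
    not shipped; pass your own to reproduce a specific peak-frequency
    distribution.)
    """
    n_freqs = CF_RANGE[1] - CF_RANGE[0] + 1
    if prob_table is None:
        probs = np.full(n_freqs, 1.0 / n_freqs)
    else:
        probs = np.asarray(prob_table, dtype=float)
        if probs.size != n_freqs:
            raise InvalidArgumentError(
                f"prob_table must have {n_freqs} entries (3-34 Hz), got {probs.size}"
            )
        if np.any(~np.isfinite(probs)) or np.any(probs < 0):
            raise InvalidArgumentError("prob_table must be nonnegative and finite")
        total = probs.sum()
        if total == 0:
            raise InvalidArgumentError("prob_table is all zero")
        probs = probs / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.choice(np.arange(CF_RANGE[0], CF_RANGE[1] + 1), p=probs))
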