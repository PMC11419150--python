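"""Core data model: signals, spectra, and simulation parameter containers.

A :class:`TimeSeries` is a uniformly sampled single-channel signal; a
:class:`PowerSpectrum` holds frequency/linear-power pairs. Simulation ground
truth travels in :class:`AperiodicParams` / :class:`PeriodicParams`, bundled
with the sampling setup in a :class:`SimSpec` so that every simulated signal
carries its own provenance (including the seed that created it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "TimeSeries",
    "PowerSpectrum",
    "AperiodicParams",
    "PeriodicParams",
    "PeakParams",
    "SimSpec",
    "MeasureRecord",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units. Must be finite and of length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidArgumentError(
                f"samples must be a 1-d sequence of length >= 2, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("samples contain non-finite values")
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class PowerSpectrum:
    """Power spectral density: strictly increasing frequencies, linear power."""

    freqs: np.ndarray
    powers: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        powers = np.asarray(self.powers, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "powers", powers)
        if freqs.ndim != 1 or freqs.size != powers.size:
            raise InvalidArgumentError("freqs and powers must be 1-d and equal length")
        if freqs.size < 2:
            raise InvalidArgumentError("spectrum needs at least 2 bins")
        if np.any(np.diff(freqs) <= 0):
            raise InvalidArgumentError("freqs must be strictly increasing")
        if not (np.all(np.isfinite(freqs)) and np.all(np.isfinite(powers))):
            raise InvalidArgumentError("spectrum contains non-finite values")

    def crop(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Return the sub-spectrum with f_lo <= f <= f_hi (inclusive)."""
        mask = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if mask.sum() < 2:
            raise InvalidArgumentError(
                f"frequency range [{f_lo}, {f_hi}] contains fewer than 2 bins"
            )
        return PowerSpectrum(self.freqs[mask], self.powers[mask])


@dataclass(frozen=True)
class AperiodicParams:
    """Aperiodic (1/f) component parameters.

    offset is log10 power at the model reference; exponent is chi in
    1/f^chi (>= 0); knee is the bend parameter k of the form
    offset - log10(k + f^chi); tau_d is the synaptic decay time (s) for the
    knee time-series simulation variant.
    """

    offset: float = 0.0
    exponent: float = 1.0
    knee: float = 0.0
    tau_d: float | None = None

    def __post_init__(self):
        if self.exponent < 0:
            raise InvalidArgumentError(f"exponent must be >= 0, got {self.exponent}")
        if self.knee < 0:
            raise InvalidArgumentError(f"knee must be >= 0, got {self.knee}")
        if self.tau_d is not None and not self.tau_d > 0:
            raise InvalidArgumentError(f"tau_d must be > 0, got {self.tau_d}")

    @property
    def knee_freq(self) -> float:
        """Knee frequency in Hz, k**(1/chi); 0 for the fixed (knee-free) form."""
        if self.knee == 0 or self.exponent == 0:
            return 0.0
        return float(self.knee ** (1.0 / self.exponent))


@dataclass(frozen=True)
class PeriodicParams:
    """Oscillation parameters: center frequency (Hz), relative power
    (variance ratio vs the aperiodic component), spectral bandwidth proxy
    (Hz), and per-cycle burst probability."""

    freq: float
    rel_power: float = 1.0
    bandwidth: float = 0.0
    burst_prob: float = 1.0

    def __post_init__(self):
        if not self.freq > 0:
            raise InvalidArgumentError(f"freq must be > 0, got {self.freq}")
        if self.rel_power < 0:
            raise InvalidArgumentError(f"rel_power must be >= 0, got {self.rel_power}")
        if self.bandwidth < 0:
            raise InvalidArgumentError(f"bandwidth must be >= 0, got {self.bandwidth}")
        if not 0 <= self.burst_prob <= 1:
            raise InvalidArgumentError(
                f"burst_prob must be in [0, 1], got {self.burst_prob}"
            )


@dataclass(frozen=True)
class PeakParams:
    """Spectral peak: center frequency (Hz), height over the aperiodic
    component in log10 units, and bandwidth (Hz; 2 x Gaussian sd)."""

    cf: float
    pw: float
    bw: float

    def __post_init__(self):
        if not self.cf > 0:
            raise InvalidArgumentError(f"cf must be > 0, got {self.cf}")
        if self.pw < 0:
            raise InvalidArgumentError(f"pw must be >= 0, got {self.pw}")
        if not self.bw > 0:
            raise InvalidArgumentError(f"bw must be > 0, got {self.bw}")

    @property
    def sd(self) -> float:
        """Gaussian standard deviation, bw / 2."""
        return self.bw / 2.0


@dataclass(frozen=True)
class SimSpec:
    """Full specification of one simulated signal (ground truth + seed)."""

    aperiodic: AperiodicParams
    periodic: PeriodicParams | None = None
    duration: float = 30.0
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self):
        n = self.duration * self.fs
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise InvalidArgumentError(
                f"duration * fs must be a positive integer, got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def with_(self, **kwargs: Any) -> "SimSpec":
        return replace(self, **kwargs)


@dataclass
class MeasureRecord:
    """One measure result with the exact settings that produced it.

    censored flags results that hit a boundary (e.g. an autocorrelation that
    never decayed below the threshold within max_lag) rather than a genuine
    estimate.
    """

    name: str
    value: float
    settings: Mapping[str, Any] = field(default_factory=dict)
    censored: bool = False
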