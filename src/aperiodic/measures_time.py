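"""Time-domain measures of aperiodic structure.

Implements the autocorrelation, fluctuation (rescaled range / DFA), fractal
dimension (Higuchi, Katz, Petrosian), complexity (Hjorth, Lempel-Ziv), and
entropy (approximate, sample, permutation / weighted permutation) measures
from their defining formulas. Defaults follow common practice for 30 s EEG
segments: autocorrelation over 250 one-sample lags; decay time over 1500
lags in steps of 2 at a 0.5 threshold; fluctuation measures over 10
log-spaced scales from 0.1 to 2.0 s; Higuchi kmax 10; entropy order 2 with
tolerance 0.2 x signal sd; permutation order 3, delay 1.

Constant (zero-variance) inputs raise :class:`DegenerateInputError` rather
than silently returning NaN; measures that can hit a boundary (decay time,
sample entropy with no matches) return a flagged :class:`MeasureRecord`.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernels import apen_phi, lz76_count, sampen_counts
from .core import MeasureRecord, TimeSeries
from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "autocorrelation",
    "ac_decay_time",
    "hurst_rs",
    "dfa",
    "fractal_dimension",
    "hjorth",
    "lempel_ziv",
    "regularity_entropy",
    "permutation_entropy",
]


def _demeaned(ts: TimeSeries) -> np.ndarray:
    x = ts.samples - ts.samples.mean()
    if x.std() == 0:
        raise DegenerateInputError("constant signal")
    return x


def autocorrelation(
    ts: TimeSeries, max_lag: int = 250, lag_step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation function at lags 0, lag_step, ..., max_lag (samples).

    Uses the biased estimator (normalized by n), computed via FFT. Returns
    (lags in samples, correlations); the value at lag 0 is 1.
    """
    if not 0 < max_lag < ts.n_samples:
        raise InvalidArgumentError(
            f"max_lag must be in (0, n_samples), got {max_lag} for n={ts.n_samples}"
        )
    if lag_step < 1:
        raise InvalidArgumentError(f"lag_step must be >= 1, got {lag_step}")
    x = _demeaned(ts)
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(x, nfft)
    full_ac = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    full_ac /= full_ac[0]
    lags = np.arange(0, max_lag + 1, lag_step)
    return lags, full_ac[lags]


def ac_decay_time(
    ts: TimeSeries, max_lag: int = 1500, lag_step: int = 2, level: float = 0.5
) -> MeasureRecord:
    """Time (s) for the autocorrelation to first decay to ``level``.

    The crossing is located at the first measured lag whose autocorrelation
    is <= level and refined by linear interpolation between the bracketing
    lags, so the estimate is continuous rather than quantized to the lag
    grid (signals whose autocorrelation collapses within the first lag step
    would otherwise all tie at one value). If the autocorrelation never
    reaches the level within max_lag, the record is censored with value
    max_lag (s).
    """
    if not 0 < level < 1:
        raise InvalidArgumentError(f"level must be in (0, 1), got {level}")
    lags, ac = autocorrelation(ts, max_lag=max_lag, lag_step=lag_step)
    settings = {"max_lag": max_lag, "lag_step": lag_step, "level": level}
    below = np.flatnonzero((ac <= level) & (lags > 0))
    if below.size == 0:
        return MeasureRecord(
            "ac_decay_time", max_lag / ts.fs, settings=settings, censored=True
        )
    i = below[0]
    lag_hi, ac_hi = lags[i], ac[i]
    lag_lo, ac_lo = lags[i - 1], ac[i - 1]  # i >= 1 since ac[0] = 1 > level
    if ac_lo == ac_hi:
        crossing = float(lag_hi)
    else:
        crossing = lag_lo + (ac_lo - level) / (ac_lo - ac_hi) * (lag_hi - lag_lo)
    return MeasureRecord("ac_decay_time", crossing / ts.fs, settings=settings)


def _log_spaced_scales(
    fs: float, n_scales: int, min_scale: float, max_scale: float, n_samples: int
) -> np.ndarray:
    if not 0 < min_scale < max_scale:
        raise InvalidArgumentError(
            f"need 0 < min_scale < max_scale, got {min_scale}, {max_scale}"
        )
    if max_scale * fs > n_samples:
        raise InvalidArgumentError(
            f"max_scale {max_scale}s exceeds signal duration {n_samples / fs}s"
        )
    scales = np.unique(
        np.round(
            np.logspace(np.log10(min_scale * fs), np.log10(max_scale * fs), n_scales)
        ).astype(int)
    )
    return scales[scales >= 4]


def hurst_rs(
    ts: TimeSeries,
    n_scales: int = 10,
    min_scale: float = 0.1,
    max_scale: float = 2.0,
) -> float:
    """Hurst exponent by rescaled-range (R/S) analysis.

    For each of ``n_scales`` log-spaced window lengths between ``min_scale``
    and ``max_scale`` seconds, the signal is split into non-overlapping
    windows; each window is mean-detrended, and the range of its cumulative
    deviation profile is divided by its standard deviation. H is the OLS
    slope of log(mean R/S) against log(window length).
    """
    x = _demeaned(ts)
    scales = _log_spaced_scales(ts.fs, n_scales, min_scale, max_scale, x.size)
    rs_values = []
    used_scales = []
    for w in scales:
        n_windows = x.size // w
        segs = x[: n_windows * w].reshape(n_windows, w)
        segs = segs - segs.mean(axis=1, keepdims=True)
        profile = np.cumsum(segs, axis=1)
        r = profile.max(axis=1) - profile.min(axis=1)
        s = segs.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        rs_values.append((r[ok] / s[ok]).mean())
        used_scales.append(w)
    if len(used_scales) < 2:
        raise DegenerateInputError("too few valid scales for R/S analysis")
    slope = np.polyfit(np.log(used_scales), np.log(rs_values), 1)[0]
    return float(slope)


def dfa(
    ts: TimeSeries,
    n_scales: int = 10,
    min_scale: float = 0.1,
    max_scale: float = 2.0,
    order: int = 1,
) -> float:
    """Detrended fluctuation analysis scaling exponent alpha.

    The profile (cumulative sum of the mean-centered signal) is split into
    non-overlapping windows at each log-spaced scale; each window is
    detrended by a polynomial of the given order and the RMS residual across
    all windows gives the fluctuation F(scale). Alpha is the OLS slope of
    log F against log scale. For colored noise, alpha relates to the
    spectral exponent chi as alpha = (chi + 1) / 2.
    """
    if order < 0:
        raise InvalidArgumentError(f"order must be >= 0, got {order}")
    x = _demeaned(ts)
    profile = np.cumsum(x)
    scales = _log_spaced_scales(ts.fs, n_scales, min_scale, max_scale, x.size)
    flucts = []
    for w in scales:
        n_windows = profile.size // w
        segs = profile[: n_windows * w].reshape(n_windows, w)
        t = np.arange(w)
        coefs = np.polynomial.polynomial.polyfit(t, segs.T, order)
        trends = np.polynomial.polynomial.polyval(t, coefs)
        resid = segs - trends
        flucts.append(np.sqrt(np.mean(resid**2)))
    flucts = np.asarray(flucts)
    if np.any(flucts == 0):
        raise DegenerateInputError("zero fluctuation at some scale")
    slope = np.polyfit(np.log(scales), np.log(flucts), 1)[0]
    return float(slope)


def _higuchi(x: np.ndarray, kmax: int) -> float:
    n = x.size
    lengths = []
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lk += dist * norm / k
        lengths.append(lk / k)
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        raise DegenerateInputError("zero curve length in Higuchi estimate")
    ks = np.arange(1, kmax + 1)
    return float(np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0])


def _katz(x: np.ndarray) -> float:
    dists = np.abs(np.diff(x))
    total_len = dists.sum()
    if total_len == 0:
        raise DegenerateInputError("zero path length in Katz estimate")
    d = np.abs(x - x[0]).max()
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / total_len)))


def _petrosian(x: np.ndarray) -> float:
    diff = np.diff(x)
    if np.all(diff == 0):
        raise DegenerateInputError("constant signal")
    n_delta = int(np.sum(np.diff(np.sign(diff[diff != 0])) != 0))
    n = x.size
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def fractal_dimension(ts: TimeSeries, method: str = "higuchi", kmax: int = 10) -> float:
    """Fractal dimension of the signal graph, in [1, 2].

    ``higuchi``: slope of log mean curve length against log(1/k) for
    decimation factors k = 1..kmax. ``katz``: log10(n) / (log10(n) +
    log10(d/L)) with L the total path length and d the maximum distance from
    the first point. ``petrosian``: log10(n) / (log10(n) + log10(n / (n +
    0.4 N_delta))) with N_delta the number of sign changes of the first
    difference.
    """
    x = _demeaned(ts)
    if method == "higuchi":
        if ts.n_samples < 3 * kmax:
            raise InvalidArgumentError(
                f"need length >= 3*kmax for Higuchi, got {ts.n_samples} < {3 * kmax}"
            )
        return _higuchi(x, kmax)
    if method == "katz":
        return _katz(x)
    if method == "petrosian":
        return _petrosian(x)
    raise InvalidArgumentError(f"unknown fractal dimension method {method!r}")


def hjorth(ts: TimeSeries) -> tuple[float, float, float]:
    """Hjorth parameters (activity, mobility, complexity).

    activity = variance; mobility = sqrt(var(dx)/var(x)); complexity =
    mobility(dx) / mobility(x).
    """
    if ts.n_samples < 3:
        raise InvalidArgumentError("need at least 3 samples")
    x = ts.samples
    var_x = x.var()
    if var_x == 0:
        raise DegenerateInputError("constant signal")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = dx.var()
    if var_dx == 0:
        raise DegenerateInputError("linear signal has zero-variance derivative")
    mobility = np.sqrt(var_dx / var_x)
    mobility_dx = np.sqrt(ddx.var() / var_dx)
    return float(var_x), float(mobility), float(mobility_dx / mobility)


def lempel_ziv(ts: TimeSeries, normalize: bool = False) -> float:
    """Lempel-Ziv (LZ76) complexity of the median-binarized signal.

    The signal is binarized at its median and the number of sub-strings in
    the LZ76 parsing is counted. With ``normalize`` the count is divided by
    n / log2(n), so long random sequences approach 1.
    """
    x = ts.samples
    binary = (x > np.median(x)).astype(np.uint8)
    count = lz76_count(binary)
    if normalize:
        n = binary.size
        return float(count / (n / np.log2(n)))
    return float(count)


def regularity_entropy(
    ts: TimeSeries,
    method: str = "sample",
    order: int = 2,
    tolerance: float | None = None,
) -> MeasureRecord:
    """Approximate or sample entropy of the signal.

    Template length ``order`` (m), Chebyshev tolerance ``tolerance`` (r);
    if r is None it defaults to 0.2 x the signal standard deviation, making
    the result invariant to affine rescaling. Sample entropy excludes
    self-matches; approximate entropy includes them. A sample-entropy
    computation with zero template matches has an undefined logarithm and is
    returned as a censored record (value = log of the number of possible
    pairs, the measure's resolution ceiling).
    """
    if method not in ("approximate", "sample"):
        raise InvalidArgumentError(f"unknown entropy method {method!r}")
    x = np.ascontiguousarray(ts.samples, dtype=np.float64)
    if x.size <= order + 1:
        raise InvalidArgumentError(
            f"need length > order+1, got {x.size} <= {order + 1}"
        )
    sd = x.std()
    if sd == 0:
        settings = {"method": method, "order": order, "tolerance": 0.0}
        return MeasureRecord(f"{method}_entropy", 0.0, settings=settings)
    r = 0.2 * sd if tolerance is None else float(tolerance)
    if not r > 0:
        raise InvalidArgumentError(f"tolerance must be > 0, got {r}")
    settings = {"method": method, "order": order, "tolerance": r}
    if method == "approximate":
        value = apen_phi(x, order, r) - apen_phi(x, order + 1, r)
        return MeasureRecord("approximate_entropy", float(value), settings=settings)
    a, b = sampen_counts(x, order, r)
    if a == 0 or b == 0:
        n_pairs = (x.size - order) * (x.size - order - 1) / 2
        return MeasureRecord(
            "sample_entropy", float(np.log(n_pairs)), settings=settings, censored=True
        )
    return MeasureRecord("sample_entropy", float(-np.log(a / b)), settings=settings)


def permutation_entropy(
    ts: TimeSeries, order: int = 3, delay: int = 1, weighted: bool = False
) -> float:
    """(Weighted) permutation entropy, normalized to [0, 1].

    Shannon entropy of the ordinal-pattern distribution over embedded
    segments of the given order and delay, normalized by log(order!). The
    weighted variant weights each segment's pattern by the segment variance.
    Ties within a segment are broken by temporal order (stable sort).
    """
    if order < 2:
        raise InvalidArgumentError(f"order must be >= 2, got {order}")
    if delay < 1:
        raise InvalidArgumentError(f"delay must be >= 1, got {delay}")
    x = ts.samples
    n_segments = x.size - (order - 1) * delay
    if n_segments < 1:
        raise InvalidArgumentError("signal too short for the requested embedding")
    idx = np.arange(n_segments)[:, None] + np.arange(order)[None, :] * delay
    segments = x[idx]
    patterns = np.argsort(segments, axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    if weighted:
        weights = segments.var(axis=1)
        if weights.sum() == 0:
            weights = np.ones(n_segments)
    else:
        weights = np.ones(n_segments)
    totals = np.bincount(codes, weights=weights)
    probs = totals[totals > 0] / weights.sum()
    entropy = -np.sum(probs * np.log(probs))
    return float(entropy / np.log(float(math.factorial(order))))
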