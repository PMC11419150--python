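"""Frequency-domain estimation of aperiodic parameters.

Power spectra are estimated with Welch's method. The aperiodic exponent can
then be measured by direct line fits in log-log space (OLS, robust linear
model, RANSAC, or a nonlinear exponential fit in semi-log space, each with
an optional alpha-band exclusion), by iterative spectral parameterization —
which jointly models the aperiodic component (power-law or knee form) and
overlying Gaussian peaks, fitting the aperiodic component on a peak-removed
spectrum — or via IRASA, which isolates the scale-free component by taking
geometric means of spectra from paired up/down-resampled copies of the
signal and median-reducing across resampling factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import signal as sp_signal
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .core import AperiodicParams, PeakParams, PowerSpectrum, TimeSeries
from .exceptions import InvalidArgumentError

__all__ = [
    "SpectralFit",
    "SpectralModel",
    "IrasaDecomposition",
    "compute_psd",
    "fit_spectral_line",
    "specparam_fit",
    "fit_aperiodic",
    "irasa_decompose",
    "irasa_exponent",
    "dominant_peak_power",
    "spectral_entropy",
    "fit_exponent_from_ts",
    "DEFAULT_HSET",
    "ALPHA_BAND",
]

# IRASA resampling factors: 1.1 to 1.95 in steps of 0.05.
DEFAULT_HSET: tuple[float, ...] = tuple(np.round(np.arange(1.1, 1.951, 0.05), 2))

# Fixed alpha-region exclusion band (Hz) for line fits that skip the
# canonical oscillatory range.
ALPHA_BAND: tuple[float, float] = (7.0, 14.0)

_LINE_METHODS = ("ols", "rlm", "ransac", "exp")


@dataclass(frozen=True)
class SpectralFit:
    """Result of a direct aperiodic line fit."""

    aperiodic: AperiodicParams
    method: str
    error: float  # RMSE of the fit in log10-power space
    settings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SpectralModel:
    """Result of a full spectral parameterization."""

    aperiodic: AperiodicParams
    peaks: tuple[PeakParams, ...]
    r_squared: float
    fit_range: tuple[float, float]
    mode: str
    success: bool = True

    @property
    def exponent(self) -> float:
        return self.aperiodic.exponent


@dataclass(frozen=True)
class IrasaDecomposition:
    """Aperiodic / periodic spectral decomposition from IRASA."""

    freqs: np.ndarray
    aperiodic_spectrum: np.ndarray
    periodic_residual: np.ndarray
    hset: tuple[float, ...]

    @property
    def aperiodic(self) -> PowerSpectrum:
        return PowerSpectrum(self.freqs, self.aperiodic_spectrum)


def compute_psd(ts: TimeSeries, seg_len: float = 2.0, overlap: float = 0.5) -> PowerSpectrum:
    """Welch power spectral density with Hann-tapered segments.

    ``seg_len`` is the segment length in seconds (frequency resolution is
    1/seg_len); ``overlap`` the fractional overlap between segments.
    """
    nperseg = int(round(seg_len * ts.fs))
    if nperseg > ts.n_samples:
        raise InvalidArgumentError(
            f"seg_len {seg_len}s exceeds signal duration {ts.duration}s"
        )
    if not 0 <= overlap < 1:
        raise InvalidArgumentError(f"overlap must be in [0, 1), got {overlap}")
    freqs, powers = sp_signal.welch(
        ts.samples,
        fs=ts.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
    )
    return PowerSpectrum(freqs, powers)


def _select_bins(
    ps: PowerSpectrum,
    frange: tuple[float, float],
    exclusion: tuple[float, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    mask = (ps.freqs >= frange[0]) & (ps.freqs <= frange[1]) & (ps.freqs > 0)
    mask &= ps.powers > 0
    if exclusion is not None:
        mask &= ~((ps.freqs >= exclusion[0]) & (ps.freqs <= exclusion[1]))
    if mask.sum() < 4:
        raise InvalidArgumentError(
            f"fewer than 4 usable bins in range {frange} after exclusion"
        )
    return ps.freqs[mask], np.log10(ps.powers[mask])


def fit_spectral_line(
    ps: PowerSpectrum,
    frange: tuple[float, float] = (1.0, 50.0),
    method: str = "ols",
    exclusion: tuple[float, float] | None = None,
    seed: int = 0,
) -> SpectralFit:
    """Fit the aperiodic exponent by a direct line fit to the spectrum.

    ``ols``, ``rlm`` (Huber robust linear model) and ``ransac`` fit
    log10(power) against log10(freq); the exponent is the negated slope.
    ``exp`` fits the same power-law form by nonlinear least squares in
    semi-log space (log10 power against linear frequency). ``exclusion``
    removes a frequency band (e.g. the alpha range) before fitting.
    """
    if method not in _LINE_METHODS:
        raise InvalidArgumentError(
            f"unknown method {method!r}; expected one of {_LINE_METHODS}"
        )
    freqs, log_powers = _select_bins(ps, frange, exclusion)
    log_freqs = np.log10(freqs)

    if method == "ols":
        slope, intercept = np.polyfit(log_freqs, log_powers, 1)
    elif method == "rlm":
        exog = sm.add_constant(log_freqs)
        res = sm.RLM(log_powers, exog, M=sm.robust.norms.HuberT()).fit()
        intercept, slope = res.params
    elif method == "ransac":
        # adaptive inlier threshold: MAD-scaled residuals of a first OLS pass
        s0, i0 = np.polyfit(log_freqs, log_powers, 1)
        resid = log_powers - (i0 + s0 * log_freqs)
        thresh = max(2.0 * 1.4826 * np.median(np.abs(resid - np.median(resid))), 1e-6)
        ransac = RANSACRegressor(
            estimator=LinearRegression(),
            residual_threshold=thresh,
            max_trials=100,
            random_state=seed,
        )
        ransac.fit(log_freqs[:, None], log_powers)
        slope = float(ransac.estimator_.coef_[0])
        intercept = float(ransac.estimator_.intercept_)
    else:  # exp: nonlinear fit of the power-law form in semi-log space
        s0, i0 = np.polyfit(log_freqs, log_powers, 1)

        def _model(f, offset, exponent):
            return offset - exponent * np.log10(f)

        params, _ = curve_fit(_model, freqs, log_powers, p0=(i0, -s0), maxfev=5000)
        intercept, slope = params[0], -params[1]

    exponent = -float(slope)
    model = float(intercept) + float(slope) * log_freqs
    rmse = float(np.sqrt(np.mean((log_powers - model) ** 2)))
    settings = {"frange": frange, "exclusion": exclusion}
    return SpectralFit(
        AperiodicParams(offset=float(intercept), exponent=max(exponent, 0.0)),
        method=method,
        error=rmse,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# spectral parameterization


def _ap_model(freqs: np.ndarray, params: Sequence[float], mode: str) -> np.ndarray:
    if mode == "fixed":
        offset, exponent = params
        return offset - exponent * np.log10(freqs)
    offset, knee, exponent = params
    return offset - np.log10(knee + freqs**exponent)


def _simple_ap_fit(
    freqs: np.ndarray, log_powers: np.ndarray, mode: str, p0=None
) -> np.ndarray:
    if mode == "fixed":
        if p0 is None:
            slope, intercept = np.polyfit(np.log10(freqs), log_powers, 1)
            p0 = (intercept, -slope)

        def model(f, offset, exponent):
            return offset - exponent * np.log10(f)

        bounds = ([-np.inf, -np.inf], [np.inf, np.inf])
    else:
        if p0 is None:
            slope, intercept = np.polyfit(np.log10(freqs), log_powers, 1)
            p0 = (intercept, 1.0, max(-slope, 0.1))

        def model(f, offset, knee, exponent):
            return offset - np.log10(knee + f**exponent)

        bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        params, _ = curve_fit(model, freqs, log_powers, p0=p0, bounds=bounds, maxfev=5000)
    return np.asarray(params, dtype=float)


def _robust_ap_fit(freqs: np.ndarray, log_powers: np.ndarray, mode: str) -> np.ndarray:
    """Aperiodic fit that ignores bins sticking up above the initial fit."""
    params = _simple_ap_fit(freqs, log_powers, mode)
    flat = log_powers - _ap_model(freqs, params, mode)
    flat = np.clip(flat, 0.0, None)
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() >= (2 if mode == "fixed" else 3):
        params = _simple_ap_fit(freqs[mask], log_powers[mask], mode, p0=tuple(params))
    return params


def _guess_bw(
    freqs: np.ndarray, flat: np.ndarray, imax: int, height: float
) -> float:
    """Estimate a peak's Gaussian sd from its half-height width."""
    half = height / 2.0
    left = imax
    while left > 0 and flat[left] > half:
        left -= 1
    right = imax
    while right < flat.size - 1 and flat[right] > half:
        right += 1
    fwhm = freqs[right] - freqs[left]
    if fwhm <= 0:
        fwhm = 2.0 * (freqs[1] - freqs[0])
    return fwhm / 2.355  # FWHM -> sd


def _gaussian(freqs: np.ndarray, cf: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((freqs - cf) ** 2) / (2.0 * sd**2))


def _multi_gaussian(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        out += _gaussian(freqs, params[i], params[i + 1], params[i + 2])
    return out


def specparam_fit(
    ps: PowerSpectrum,
    frange: tuple[float, float] = (1.0, 50.0),
    mode: str = "fixed",
    max_n_peaks: int = 8,
    peak_width_limits: tuple[float, float] = (1.0, 8.0),
    peak_threshold: float = 2.0,
    min_peak_height: float = 0.05,
) -> SpectralModel:
    """Parameterize a power spectrum as aperiodic component plus peaks.

    Algorithm: (1) robust initial aperiodic fit (fit, drop bins far above
    the fit, refit); (2) flatten the spectrum by subtracting it; (3)
    iteratively take the maximum of the flattened spectrum and subtract a
    Gaussian guess there, until ``max_n_peaks`` is reached or the next
    maximum falls below max(``peak_threshold`` x sd of the flattened
    spectrum, ``min_peak_height``); (4) refit all Gaussians jointly;
    (5) subtract the peaks from the original spectrum and refit the
    aperiodic component (``fixed``: offset - exponent*log10 f; ``knee``:
    offset - log10(knee + f^exponent)); (6) report R^2 between model and
    data in log10 space.

    Optimizer non-convergence yields a flagged (``success=False``) result
    rather than an exception.
    """
    if mode not in ("fixed", "knee"):
        raise InvalidArgumentError(f"mode must be 'fixed' or 'knee', got {mode!r}")
    freqs, log_powers = _select_bins(ps, frange, None)
    failed = SpectralModel(
        AperiodicParams(offset=np.nan, exponent=0.0, knee=0.0),
        peaks=(),
        r_squared=np.nan,
        fit_range=frange,
        mode=mode,
        success=False,
    )
    try:
        ap_params = _robust_ap_fit(freqs, log_powers, mode)
    except (RuntimeError, ValueError):
        return failed

    flat = log_powers - _ap_model(freqs, ap_params, mode)

    # iterative peak search on a working copy of the flattened spectrum
    guesses: list[tuple[float, float, float]] = []
    flat_iter = flat.copy()
    sd_lo, sd_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    for _ in range(max_n_peaks):
        imax = int(np.argmax(flat_iter))
        height = flat_iter[imax]
        if height <= max(peak_threshold * flat_iter.std(), min_peak_height):
            break
        cf = float(freqs[imax])
        sd = float(np.clip(_guess_bw(freqs, flat_iter, imax, height), sd_lo, sd_hi))
        guesses.append((cf, float(height), sd))
        flat_iter -= _gaussian(freqs, cf, height, sd)

    peaks: tuple[PeakParams, ...] = ()
    peak_model = np.zeros_like(freqs)
    if guesses:
        p0 = np.ravel(guesses)
        lo, hi = [], []
        for cf, height, sd in guesses:
            lo += [max(frange[0], cf - 2 * sd), 0.0, sd_lo * 0.75]
            hi += [min(frange[1], cf + 2 * sd), np.inf, sd_hi * 1.25]
        p0 = np.clip(p0, lo, hi)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                params, _ = curve_fit(
                    _multi_gaussian, freqs, flat, p0=p0, bounds=(lo, hi), maxfev=5000
                )
        except (RuntimeError, ValueError):
            return failed
        fitted = [
            PeakParams(cf=params[i], pw=params[i + 1], bw=2.0 * params[i + 2])
            for i in range(0, len(params), 3)
        ]
        peaks = tuple(p for p in fitted if frange[0] <= p.cf <= frange[1] and p.pw > 0)
        for p in peaks:
            peak_model += _gaussian(freqs, p.cf, p.pw, p.sd)

    # final aperiodic fit on the peak-removed spectrum
    try:
        ap_params = _robust_ap_fit(freqs, log_powers - peak_model, mode)
    except (RuntimeError, ValueError):
        return failed

    model = _ap_model(freqs, ap_params, mode) + peak_model
    ss_res = np.sum((log_powers - model) ** 2)
    ss_tot = np.sum((log_powers - log_powers.mean()) ** 2)
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    if mode == "fixed":
        aperiodic = AperiodicParams(
            offset=float(ap_params[0]), exponent=max(float(ap_params[1]), 0.0)
        )
    else:
        aperiodic = AperiodicParams(
            offset=float(ap_params[0]),
            knee=max(float(ap_params[1]), 0.0),
            exponent=max(float(ap_params[2]), 0.0),
        )
    return SpectralModel(
        aperiodic=aperiodic,
        peaks=peaks,
        r_squared=float(r_squared),
        fit_range=frange,
        mode=mode,
    )


def fit_aperiodic(
    ps: PowerSpectrum, frange: tuple[float, float] = (1.0, 50.0), mode: str = "fixed"
) -> AperiodicParams:
    """Robust aperiodic-only fit of a spectrum (no peak modeling).

    This is the aperiodic stage of :func:`specparam_fit` applied directly to
    any spectrum — e.g. the aperiodic component isolated by IRASA.
    """
    if mode not in ("fixed", "knee"):
        raise InvalidArgumentError(f"mode must be 'fixed' or 'knee', got {mode!r}")
    freqs, log_powers = _select_bins(ps, frange, None)
    params = _robust_ap_fit(freqs, log_powers, mode)
    if mode == "fixed":
        return AperiodicParams(offset=float(params[0]), exponent=max(float(params[1]), 0.0))
    return AperiodicParams(
        offset=float(params[0]),
        knee=max(float(params[1]), 0.0),
        exponent=max(float(params[2]), 0.0),
    )


# ---------------------------------------------------------------------------
# IRASA


def irasa_decompose(
    ts: TimeSeries,
    frange: tuple[float, float] = (1.0, 50.0),
    hset: Sequence[float] | None = None,
    seg_len: float = 2.0,
    overlap: float = 0.5,
) -> IrasaDecomposition:
    """Separate aperiodic and periodic spectral components via IRASA.

    For each resampling factor h, the signal is resampled up by h and down
    by h (rational polyphase resampling). Spectra of both copies are then
    computed with the *original* sampling rate left in place, which shifts
    any periodic peak to h- and 1/h-multiples of its frequency while leaving
    scale-free structure invariant, and lands both spectra on the original
    frequency grid. The geometric mean of each (h, 1/h) pair suppresses the
    displaced peaks, and the median across the h-set is the aperiodic
    spectrum; the periodic residual is the original PSD minus it.
    """
    hset = tuple(DEFAULT_HSET if hset is None else hset)
    if any(h <= 1 for h in hset):
        raise InvalidArgumentError("all resampling factors must be > 1")
    nperseg = int(round(seg_len * ts.fs))
    if ts.n_samples < nperseg * max(hset):
        raise InvalidArgumentError("signal too short for the requested resampling")

    psd = compute_psd(ts, seg_len=seg_len, overlap=overlap)
    mask = (psd.freqs >= frange[0]) & (psd.freqs <= frange[1])
    if mask.sum() < 4:
        raise InvalidArgumentError(f"fewer than 4 bins in range {frange}")
    noverlap = int(round(overlap * nperseg))

    geomeans = []
    for h in hset:
        frac = Fraction(h).limit_denominator(100)
        up = sp_signal.resample_poly(ts.samples, frac.numerator, frac.denominator)
        down = sp_signal.resample_poly(ts.samples, frac.denominator, frac.numerator)
        _, p_up = sp_signal.welch(
            up, fs=ts.fs, window="hann", nperseg=nperseg, noverlap=noverlap
        )
        _, p_down = sp_signal.welch(
            down, fs=ts.fs, window="hann", nperseg=nperseg, noverlap=noverlap
        )
        geomeans.append(np.sqrt(p_up * p_down))

    aperiodic = np.median(np.vstack(geomeans), axis=0)
    return IrasaDecomposition(
        freqs=psd.freqs[mask],
        aperiodic_spectrum=aperiodic[mask],
        periodic_residual=psd.powers[mask] - aperiodic[mask],
        hset=hset,
    )


def irasa_exponent(
    ts: TimeSeries,
    frange: tuple[float, float] = (1.0, 50.0),
    mode: str = "fixed",
    hset: Sequence[float] | None = None,
) -> AperiodicParams:
    """IRASA decomposition followed by an aperiodic fit of the isolated
    aperiodic spectrum (the standard way to get an exponent from IRASA)."""
    decomp = irasa_decompose(ts, frange=frange, hset=hset)
    return fit_aperiodic(decomp.aperiodic, frange=frange, mode=mode)


# ---------------------------------------------------------------------------
# misc spectral measures


def dominant_peak_power(model: SpectralModel, band: tuple[float, float]) -> float:
    """Power of the dominant (highest) fitted peak within a band; 0 if none."""
    if not model.success:
        raise InvalidArgumentError("cannot read peaks from a failed fit")
    in_band = [p.pw for p in model.peaks if band[0] <= p.cf <= band[1]]
    return max(in_band) if in_band else 0.0


def spectral_entropy(ps: PowerSpectrum) -> float:
    """Shannon entropy of the power-normalized spectrum, normalized to [0, 1].

    A flat spectrum gives 1; a single nonzero bin gives 0.
    """
    powers = ps.powers
    if np.any(powers < 0):
        raise InvalidArgumentError("powers must be nonnegative")
    total = powers.sum()
    if total == 0:
        raise InvalidArgumentError("all-zero spectrum")
    p = powers / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(ps.freqs.size))


def fit_exponent_from_ts(
    ts: TimeSeries,
    frange: tuple[float, float] = (1.0, 50.0),
    method: str = "specparam",
    mode: str = "fixed",
    seg_len: float = 2.0,
) -> float:
    """Convenience: Welch PSD then an exponent estimate by the named method.

    ``method`` is one of 'specparam', 'irasa', or any direct line-fit method
    ('ols', 'rlm', 'ransac', 'exp').
    """
    if method == "irasa":
        return irasa_exponent(ts, frange=frange, mode=mode).exponent
    psd = compute_psd(ts, seg_len=seg_len)
    if method == "specparam":
        model = specparam_fit(psd, frange=frange, mode=mode)
        if not model.success:
            raise InvalidArgumentError("spectral parameterization failed")
        return model.exponent
    return fit_spectral_line(psd, frange=frange, method=method).aperiodic.exponent
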