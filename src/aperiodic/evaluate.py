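"""Method-comparison harness.

Runs batteries of measures over collections of simulated signals, collecting
results and ground truth into a tidy table (one row per signal), and
provides the comparison statistics used to relate methods to each other:
error summaries with two-sample t-tests and Cohen's d, pairwise Spearman
correlation matrices, case-resampling bootstrap confidence intervals and
correlation-difference tests, and semi-partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MeasureRecord, SimSpec, TimeSeries
from .exceptions import InvalidArgumentError
from . import measures_freq, measures_time

__all__ = [
    "MEASURES",
    "FEATURED_MEASURES",
    "run_sweep",
    "ErrorStats",
    "error_stats",
    "CorrelationMatrix",
    "spearman_matrix",
    "BootstrapCorr",
    "bootstrap_corr",
    "bootstrap_corr_diff",
    "SemiPartial",
    "semipartial_corr",
]


def _as_record(name: str, value: float, **settings) -> MeasureRecord:
    return MeasureRecord(name, float(value), settings=settings)


def _m_ac_decay(ts: TimeSeries) -> MeasureRecord:
    # hold the measured window fixed in time (6 s, i.e. 1500 lags at 250 Hz)
    # so the measure spans the same autocorrelation range at any rate
    return measures_time.ac_decay_time(ts, max_lag=int(round(6.0 * ts.fs)))


def _m_hurst(ts: TimeSeries) -> MeasureRecord:
    return _as_record("hurst", measures_time.hurst_rs(ts))


def _m_dfa(ts: TimeSeries) -> MeasureRecord:
    return _as_record("dfa", measures_time.dfa(ts))


def _m_higuchi(ts: TimeSeries) -> MeasureRecord:
    return _as_record("higuchi", measures_time.fractal_dimension(ts, "higuchi"), kmax=10)


def _m_katz(ts: TimeSeries) -> MeasureRecord:
    return _as_record("katz", measures_time.fractal_dimension(ts, "katz"))


def _m_petrosian(ts: TimeSeries) -> MeasureRecord:
    return _as_record("petrosian", measures_time.fractal_dimension(ts, "petrosian"))


def _m_hjorth_mobility(ts: TimeSeries) -> MeasureRecord:
    return _as_record("hjorth_mobility", measures_time.hjorth(ts)[1])


def _m_hjorth_complexity(ts: TimeSeries) -> MeasureRecord:
    return _as_record("hjorth_complexity", measures_time.hjorth(ts)[2])


def _m_lempel_ziv(ts: TimeSeries) -> MeasureRecord:
    return _as_record("lempel_ziv", measures_time.lempel_ziv(ts), normalize=False)


def _m_approximate_entropy(ts: TimeSeries) -> MeasureRecord:
    return measures_time.regularity_entropy(ts, method="approximate")


def _m_sample_entropy(ts: TimeSeries) -> MeasureRecord:
    return measures_time.regularity_entropy(ts, method="sample")


def _m_permutation_entropy(ts: TimeSeries) -> MeasureRecord:
    return _as_record(
        "permutation_entropy", measures_time.permutation_entropy(ts), order=3, delay=1
    )


def _m_wpermutation_entropy(ts: TimeSeries) -> MeasureRecord:
    return _as_record(
        "weighted_permutation_entropy",
        measures_time.permutation_entropy(ts, weighted=True),
        order=3,
        delay=1,
    )


def _m_exponent(ts: TimeSeries) -> MeasureRecord:
    value = measures_freq.fit_exponent_from_ts(ts, method="specparam")
    return _as_record("exponent", value, method="specparam", frange=(1.0, 50.0))


def _m_exponent_irasa(ts: TimeSeries) -> MeasureRecord:
    value = measures_freq.fit_exponent_from_ts(ts, method="irasa")
    return _as_record("exponent_irasa", value, method="irasa", frange=(1.0, 50.0))


def _m_spectral_entropy(ts: TimeSeries) -> MeasureRecord:
    return _as_record("spectral_entropy", measures_freq.spectral_entropy(
        measures_freq.compute_psd(ts)))


#: Registry of measure name -> callable(TimeSeries) -> MeasureRecord.
MEASURES: Mapping[str, Callable[[TimeSeries], MeasureRecord]] = {
    "ac_decay_time": _m_ac_decay,
    "hurst": _m_hurst,
    "dfa": _m_dfa,
    "higuchi": _m_higuchi,
    "katz": _m_katz,
    "petrosian": _m_petrosian,
    "hjorth_mobility": _m_hjorth_mobility,
    "hjorth_complexity": _m_hjorth_complexity,
    "lempel_ziv": _m_lempel_ziv,
    "approximate_entropy": _m_approximate_entropy,
    "sample_entropy": _m_sample_entropy,
    "permutation_entropy": _m_permutation_entropy,
    "weighted_permutation_entropy": _m_wpermutation_entropy,
    "spectral_entropy": _m_spectral_entropy,
    "exponent": _m_exponent,
    "exponent_irasa": _m_exponent_irasa,
}

#: The featured battery used throughout the method comparisons: one or two
#: representatives per measure family plus the fitted spectral exponent.
FEATURED_MEASURES: tuple[str, ...] = (
    "ac_decay_time",
    "hurst",
    "dfa",
    "higuchi",
    "katz",
    "hjorth_complexity",
    "lempel_ziv",
    "sample_entropy",
    "permutation_entropy",
    "exponent",
)


def run_sweep(
    signals: Sequence[tuple[SimSpec, TimeSeries]],
    measures: Sequence[str],
) -> pd.DataFrame:
    """Apply a battery of measures to a collection of simulated signals.

    Returns one row per signal with its ground-truth parameters
    (``sim_exponent``, ``sim_tau_d``, ``sim_freq``, ``sim_rel_power``,
    ``sim_bandwidth``, ``sim_burst_prob``, ``has_oscillation``, ``seed``),
    one column per measure, and a ``<measure>__censored`` flag column for
    each. A measure that fails on a signal is recorded as NaN with the flag
    set — never silently dropped.
    """
    if len(signals) == 0:
        raise InvalidArgumentError("empty signal collection")
    if len(measures) == 0:
        raise InvalidArgumentError("empty measure list")
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise InvalidArgumentError(
            f"unknown measures {unknown}; known: {sorted(MEASURES)}"
        )
    rows = []
    for spec, ts in signals:
        row: dict[str, object] = {
            "sim_exponent": spec.aperiodic.exponent,
            "sim_tau_d": spec.aperiodic.tau_d,
            "sim_freq": spec.periodic.freq if spec.periodic else np.nan,
            "sim_rel_power": spec.periodic.rel_power if spec.periodic else 0.0,
            "sim_bandwidth": spec.periodic.bandwidth if spec.periodic else np.nan,
            "sim_burst_prob": spec.periodic.burst_prob if spec.periodic else np.nan,
            "has_oscillation": spec.periodic is not None
            and spec.periodic.rel_power > 0,
            "seed": spec.seed,
        }
        for name in measures:
            try:
                record = MEASURES[name](ts)
                row[name] = record.value
                row[f"{name}__censored"] = record.censored
            except Exception:
                row[name] = np.nan
                row[f"{name}__censored"] = True
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error statistics


@dataclass(frozen=True)
class ErrorStats:
    """Summary of an estimator's error distribution, optionally compared to
    a reference method's absolute errors by two-sample t-test / Cohen's d."""

    mean_error: float
    sd_error: float
    mean_abs_error: float
    n: int
    t_stat: float = np.nan
    p_value: float = np.nan
    cohens_d: float = np.nan
    degenerate: bool = False


def error_stats(
    estimates: Sequence[float],
    truth: Sequence[float],
    reference_errors: Sequence[float] | None = None,
) -> ErrorStats:
    """Errors (estimate - truth), with an optional comparison of absolute
    errors against a reference method.

    Cohen's d uses the pooled standard deviation; if both distributions have
    zero variance the comparison is degenerate and d is reported as an
    infinite-effect sentinel (0 when the means are also equal).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise InvalidArgumentError("estimates and truth must have equal length")
    if est.size < 2:
        raise InvalidArgumentError("need at least 2 values")
    errors = est - tru
    abs_errors = np.abs(errors)
    base = dict(
        mean_error=float(errors.mean()),
        sd_error=float(errors.std(ddof=1)),
        mean_abs_error=float(abs_errors.mean()),
        n=est.size,
    )
    if reference_errors is None:
        return ErrorStats(**base)
    ref = np.abs(np.asarray(reference_errors, dtype=float))
    t_stat, p_value = stats.ttest_ind(abs_errors, ref)
    n1, n2 = abs_errors.size, ref.size
    pooled_var = (
        (n1 - 1) * abs_errors.var(ddof=1) + (n2 - 1) * ref.var(ddof=1)
    ) / (n1 + n2 - 2)
    diff = abs_errors.mean() - ref.mean()
    if pooled_var == 0:
        d = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
        return ErrorStats(**base, t_stat=float(t_stat), p_value=float(p_value),
                          cohens_d=d, degenerate=True)
    return ErrorStats(
        **base,
        t_stat=float(t_stat),
        p_value=float(p_value),
        cohens_d=float(diff / np.sqrt(pooled_var)),
    )


# ---------------------------------------------------------------------------
# correlation machinery


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman correlations: symmetric r matrix with unit
    diagonal, the per-pair sample sizes, and flags for undefined entries
    (constant columns)."""

    r: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame

    def min_abs_offdiag(self) -> float:
        vals = self.r.to_numpy(dtype=float).copy()
        np.fill_diagonal(vals, np.nan)
        return float(np.nanmin(np.abs(vals)))

    def max_abs_offdiag(self) -> float:
        vals = self.r.to_numpy(dtype=float).copy()
        np.fill_diagonal(vals, np.nan)
        return float(np.nanmax(np.abs(vals)))


def spearman_matrix(table: pd.DataFrame, columns: Sequence[str]) -> CorrelationMatrix:
    """Pairwise Spearman correlation matrix over the given columns.

    Rows with a missing value in either member of a pair are excluded
    pairwise (not listwise). A constant column yields an undefined r,
    recorded as NaN with its flag set.
    """
    cols = list(columns)
    k = len(cols)
    r = np.eye(k)
    n = np.zeros((k, k), dtype=int)
    flags = np.zeros((k, k), dtype=bool)
    for i in range(k):
        n[i, i] = table[cols[i]].notna().sum()
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                r[i, j] = r[j, i] = np.nan
                flags[i, j] = flags[j, i] = True
                continue
            x, y = pair[cols[i]].to_numpy(), pair[cols[j]].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                r[i, j] = r[j, i] = np.nan
                flags[i, j] = flags[j, i] = True
                continue
            rho = stats.spearmanr(x, y).statistic
            r[i, j] = r[j, i] = rho
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        flags=pd.DataFrame(flags, index=idx, columns=idx),
    )


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    out = np.full(x.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _bootstrap_spearman_dist(
    arrays: Sequence[np.ndarray], n_resamples: int, seed: int
) -> list[np.ndarray]:
    """Case-resampled rank matrices for each input array (shared indices)."""
    rng = np.random.default_rng(seed)
    n = arrays[0].size
    idx = rng.integers(0, n, size=(n_resamples, n))
    return [_rank_rows(a[idx]) for a in arrays]


@dataclass(frozen=True)
class BootstrapCorr:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int


def _two_sided_empirical_p(dist: np.ndarray) -> float:
    dist = dist[np.isfinite(dist)]
    if dist.size == 0:
        return np.nan
    p = 2.0 * min(np.mean(dist <= 0), np.mean(dist >= 0))
    return float(np.clip(p, 1.0 / dist.size, 1.0))


def bootstrap_corr(
    x: Sequence[float],
    y: Sequence[float],
    n_resamples: int = 5000,
    ci: float = 95.0,
    seed: int = 0,
) -> BootstrapCorr:
    """Spearman correlation with a percentile bootstrap CI.

    Paired cases are resampled with replacement ``n_resamples`` times; the
    CI is the percentile interval of the resampled correlation distribution
    and the p-value is the two-sided empirical probability of the
    distribution crossing zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 10:
        raise InvalidArgumentError(f"need n >= 10, got {x.size}")
    r = float(stats.spearmanr(x, y).statistic)
    rx, ry = _bootstrap_spearman_dist([x, y], n_resamples, seed)
    dist = _rowwise_pearson(rx, ry)
    lo, hi = np.nanpercentile(dist, [(100 - ci) / 2.0, 100 - (100 - ci) / 2.0])
    return BootstrapCorr(
        r=r,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=_two_sided_empirical_p(dist),
        n_resamples=n_resamples,
    )


def bootstrap_corr_diff(
    x: Sequence[float],
    y1: Sequence[float],
    y2: Sequence[float],
    n_resamples: int = 5000,
    seed: int = 0,
) -> float:
    """Two-sided empirical p for a difference between corr(x, y1) and
    corr(x, y2), resampling cases jointly."""
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.size == y1.size == y2.size):
        raise InvalidArgumentError("x, y1, y2 must have equal length")
    if x.size < 10:
        raise InvalidArgumentError(f"need n >= 10, got {x.size}")
    rx, r1, r2 = _bootstrap_spearman_dist([x, y1, y2], n_resamples, seed)
    dist = _rowwise_pearson(rx, r1) - _rowwise_pearson(rx, r2)
    return _two_sided_empirical_p(dist)


@dataclass(frozen=True)
class SemiPartial:
    r: float
    full_r: float
    degenerate: bool = False


def semipartial_corr(
    target: Sequence[float],
    measure: Sequence[float],
    control: Sequence[float],
) -> SemiPartial:
    """Spearman semi-partial correlation of target with measure, after
    regressing the control out of the measure only.

    All variables are rank-transformed; the control's (rank) linear
    contribution is removed from the measure and the residual is correlated
    with the target. A constant control leaves the full correlation
    (flagged); a residual with no variance (control identical to measure)
    returns a flagged r = 0 sentinel.
    """
    t = np.asarray(target, dtype=float)
    m = np.asarray(measure, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (t.size == m.size == c.size):
        raise InvalidArgumentError("target, measure, control must have equal length")
    if t.size < 4:
        raise InvalidArgumentError(f"need n >= 4, got {t.size}")
    full_r = float(stats.spearmanr(t, m).statistic)
    rc = stats.rankdata(c)
    rm = stats.rankdata(m)
    if np.all(rc == rc[0]):
        return SemiPartial(r=full_r, full_r=full_r, degenerate=True)
    beta = np.polyfit(rc, rm, 1)
    resid = rm - np.polyval(beta, rc)
    if np.allclose(resid, resid[0]):
        return SemiPartial(r=0.0, full_r=full_r, degenerate=True)
    return SemiPartial(
        r=float(stats.spearmanr(t, resid).statistic), full_r=full_r
    )
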