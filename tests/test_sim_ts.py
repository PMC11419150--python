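import numpy as np
import pytest

from aperiodic import sim_ts
from aperiodic.core import AperiodicParams, PeriodicParams, SimSpec
from aperiodic.exceptions import InvalidArgumentError
from aperiodic.measures_freq import compute_psd, specparam_fit


def _ols_exponent(ts, frange=(1.0, 50.0)):
    """Independent oracle: OLS log-log slope of the Welch spectrum."""
    psd = compute_psd(ts)
    mask = (psd.freqs >= frange[0]) & (psd.freqs <= frange[1])
    slope = np.polyfit(
        np.log10(psd.freqs[mask]), np.log10(psd.powers[mask]), 1
    )[0]
    return -slope


class TestSimPowerlaw:
    def test_unit_variance_zero_mean(self):
        ts = sim_ts.sim_powerlaw(7500, 250.0, 1.5, seed=0)
        assert ts.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert ts.samples.var() == pytest.approx(1.0, rel=1e-12)

    def test_white_noise_has_flat_spectrum(self):
        ts = sim_ts.sim_powerlaw(7500, 250.0, 0.0, seed=1)
        assert _ols_exponent(ts) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("chi", [0.5, 1.0, 2.0, 3.0])
    def test_spectral_exponent_matches_target(self, chi):
        # average over a few realizations to beat single-spectrum noise
        fits = [
            _ols_exponent(sim_ts.sim_powerlaw(7500, 250.0, chi, seed=s))
            for s in range(5)
        ]
        assert np.mean(fits) == pytest.approx(chi, abs=0.1)

    def test_first_difference_drops_exponent_by_two(self):
        from aperiodic.core import TimeSeries

        ts = sim_ts.sim_powerlaw(7500, 250.0, 2.0, seed=2)
        diff = TimeSeries(np.diff(ts.samples), ts.fs)
        assert _ols_exponent(diff) == pytest.approx(0.0, abs=0.15)

    def test_exponent_recovery_across_grid(self):
        # mean fitted exponent within 0.1 of target for every grid value
        for chi in sim_ts.EXPONENT_GRID:
            fits = [
                _ols_exponent(sim_ts.sim_powerlaw(7500, 250.0, chi, seed=100 + s))
                for s in range(20)
            ]
            assert abs(np.mean(fits) - chi) < 0.1, f"chi={chi}"

    def test_determinism_and_validation(self):
        a = sim_ts.sim_powerlaw(1024, 250.0, 1.0, seed=7)
        b = sim_ts.sim_powerlaw(1024, 250.0, 1.0, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        with pytest.raises(InvalidArgumentError):
            sim_ts.sim_powerlaw(8, 250.0, 1.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            sim_ts.sim_powerlaw(1024, -250.0, 1.0, seed=0)


class TestSimSynapticKnee:
    @pytest.mark.parametrize("tau_d", sim_ts.TAU_GRID)
    def test_valid_series_for_tau_grid(self, tau_d):
        ts = sim_ts.sim_synaptic_knee(7500, 500.0, tau_d, seed=0)
        assert ts.n_samples == 7500
        assert ts.samples.var() == pytest.approx(1.0, rel=1e-9)

    def test_high_frequency_slope_is_two(self):
        # above the knee, the Lorentzian falls as 1/f^2
        ts = sim_ts.sim_synaptic_knee(15000, 500.0, 0.015, seed=3)
        psd = compute_psd(ts)
        mask = (psd.freqs > 30) & (psd.freqs < 100)
        slope = np.polyfit(np.log10(psd.freqs[mask]), np.log10(psd.powers[mask]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.25)

    def test_knee_frequency_near_analytic_corner(self):
        # f_knee = 1 / (2 pi tau_d) for an exponential kernel
        ts = sim_ts.sim_synaptic_knee(15000, 500.0, 0.015, seed=4)
        model = specparam_fit(
            compute_psd(ts), frange=(1.0, 100.0), mode="knee",
            max_n_peaks=12, min_peak_height=0.1,
        )
        assert model.success
        expected = 1.0 / (2.0 * np.pi * 0.015)
        assert model.aperiodic.knee_freq == pytest.approx(expected, rel=0.3)

    def test_fitted_knee_decreases_with_tau(self):
        knee_freqs = []
        for tau_d in sim_ts.TAU_GRID:
            ts = sim_ts.sim_synaptic_knee(15000, 500.0, tau_d, seed=5)
            model = specparam_fit(
                compute_psd(ts), frange=(1.0, 100.0), mode="knee",
                max_n_peaks=12, min_peak_height=0.1,
            )
            knee_freqs.append(model.aperiodic.knee_freq)
        assert all(np.diff(knee_freqs) < 0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_ts.sim_synaptic_knee(1000, 250.0, 0.0, seed=0)


class TestSimOscillation:
    def test_pure_tone_peaks_at_cf(self):
        osc = sim_ts.sim_oscillation(7500, 250.0, PeriodicParams(freq=10.0), seed=0)
        psd = compute_psd(osc)
        assert psd.freqs[np.argmax(psd.powers)] == pytest.approx(10.0, abs=0.5)

    def test_burst_prob_zero_gives_silence(self):
        osc = sim_ts.sim_oscillation(
            7500, 250.0, PeriodicParams(freq=10.0, burst_prob=0.0), seed=1
        )
        assert np.all(osc.samples == 0.0)

    def test_burst_fraction_matches_probability(self):
        # count present cycles against the binomial expectation
        osc = sim_ts.sim_oscillation(
            75000, 250.0, PeriodicParams(freq=10.0, burst_prob=0.5), seed=2
        )
        n_cycles = 75000 // 25
        env = np.abs(osc.samples).reshape(n_cycles, 25).max(axis=1)
        frac = np.mean(env > 0.5)
        sd = np.sqrt(0.25 / n_cycles)
        assert abs(frac - 0.5) < 4 * sd

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_ts.sim_oscillation(1000, 250.0, PeriodicParams(freq=125.0), seed=0)

    def test_bandwidth_broadens_spectral_peak(self):
        def peak_width(bw):
            osc = sim_ts.sim_oscillation(
                15000, 250.0, PeriodicParams(freq=10.0, bandwidth=bw), seed=3
            )
            psd = compute_psd(osc, seg_len=4.0)
            mask = (psd.freqs > 5) & (psd.freqs < 15)
            p = psd.powers[mask]
            return np.sum(p > p.max() / 2.0)

        assert peak_width(2.0) > peak_width(0.0)


class TestCombineSignals:
    def test_zero_rel_power_returns_normalized_aperiodic(self):
        ap = sim_ts.sim_powerlaw(7500, 250.0, 1.0, seed=4)
        osc = sim_ts.sim_oscillation(7500, 250.0, PeriodicParams(freq=10.0), seed=5)
        out = sim_ts.combine_signals(ap, osc, 0.0)
        expected = (ap.samples - ap.samples.mean()) / ap.samples.std()
        np.testing.assert_array_equal(out.samples, expected)

    def test_variance_additivity_for_uncorrelated_components(self):
        ap = sim_ts.sim_powerlaw(75000, 250.0, 1.0, seed=6)
        osc = sim_ts.sim_oscillation(75000, 250.0, PeriodicParams(freq=10.0), seed=7)
        out = sim_ts.combine_signals(ap, osc, 1.0)
        assert out.samples.var() == pytest.approx(2.0, abs=0.1)

    def test_peak_power_grows_with_rel_power(self):
        ap = sim_ts.sim_powerlaw(7500, 250.0, 1.0, seed=8)
        osc = sim_ts.sim_oscillation(7500, 250.0, PeriodicParams(freq=10.0), seed=9)

        def peak_power(rel):
            psd = compute_psd(sim_ts.combine_signals(ap, osc, rel))
            return psd.powers[np.argmin(np.abs(psd.freqs - 10.0))]

        heights = [peak_power(rel) for rel in (0.0, 0.5, 1.0, 1.5, 2.0)]
        assert all(np.diff(heights) > 0)

    def test_mismatched_inputs_rejected(self):
        ap = sim_ts.sim_powerlaw(1000, 250.0, 1.0, seed=10)
        osc = sim_ts.sim_oscillation(999, 250.0, PeriodicParams(freq=10.0), seed=11)
        with pytest.raises(InvalidArgumentError):
            sim_ts.combine_signals(ap, osc, 1.0)


class TestBatchGenerators:
    def test_sweep_shape_and_labels(self):
        base = SimSpec(aperiodic=AperiodicParams(), duration=2.0, fs=250.0, seed=0)
        out = sim_ts.make_param_sweep("exponent", sim_ts.EXPONENT_GRID, 3, base)
        assert len(out) == len(sim_ts.EXPONENT_GRID) * 3
        exps = {spec.aperiodic.exponent for spec, _ in out}
        assert exps == set(sim_ts.EXPONENT_GRID)

    def test_empty_grid_gives_empty_collection(self):
        base = SimSpec(aperiodic=AperiodicParams(), duration=2.0, fs=250.0, seed=0)
        assert sim_ts.make_param_sweep("exponent", [], 3, base) == []

    def test_unknown_parameter_rejected(self):
        base = SimSpec(aperiodic=AperiodicParams(), duration=2.0, fs=250.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            sim_ts.make_param_sweep("wavelength", [1.0], 1, base)

    def test_comparison_set_composition(self):
        out = sim_ts.make_comparison_set(
            50, frac_aperiodic=0.3, seed=3, duration=2.0, fs=250.0
        )
        assert len(out) == 50
        n_aperiodic = sum(1 for spec, _ in out if spec.periodic is None)
        assert n_aperiodic == 15
        for spec, _ in out:
            assert 0.0 <= spec.aperiodic.exponent <= 2.5
            if spec.periodic is not None:
                assert 5.0 <= spec.periodic.freq <= 35.0
                assert 0.1 <= spec.periodic.rel_power <= 1.0

    def test_comparison_set_fully_aperiodic(self):
        out = sim_ts.make_comparison_set(
            10, frac_aperiodic=1.0, seed=4, duration=2.0, fs=250.0
        )
        assert all(spec.periodic is None for spec, _ in out)

    def test_comparison_set_determinism(self):
        a = sim_ts.make_comparison_set(8, seed=5, duration=2.0, fs=250.0)
        b = sim_ts.make_comparison_set(8, seed=5, duration=2.0, fs=250.0)
        for (_, ts_a), (_, ts_b) in zip(a, b):
            np.testing.assert_array_equal(ts_a.samples, ts_b.samples)

    def test_subset_reproducible_from_spec_seed(self):
        # per-signal seeds are counter-derived: any signal can be rebuilt alone
        out = sim_ts.make_comparison_set(6, seed=6, duration=2.0, fs=250.0)
        spec, ts = out[4]
        np.testing.assert_array_equal(
            sim_ts.simulate_from_spec(spec).samples, ts.samples
        )
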