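import numpy as np
import pytest

from qifbalance.observables import (
    burst_delay,
    coherence_rho,
    fundamental_frequencies,
    isi_cv,
    population_rate_trace,
    power_spectrum,
    rate_distribution,
)
from qifbalance.records import SpikeRaster


def _raster_from_trains(trains_e, N_e=None, N_i=1, duration=None):
    times, neuron, pop = [], [], []
    for j, tr in enumerate(trains_e):
        times.extend(tr)
        neuron.extend([j] * len(tr))
        pop.extend([0] * len(tr))
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    neuron = np.asarray(neuron, int)[order]
    pop = np.asarray(pop, int)[order]
    if N_e is None:
        N_e = len(trains_e)
    if duration is None:
        duration = float(times.max()) + 1.0 if len(times) else 1.0
    return SpikeRaster(times, neuron, pop, N_e, N_i, duration)


class TestCoherenceRho:
    def test_identical_traces_are_fully_coherent(self):
        t = np.linspace(0, 10, 500)
        v = np.tile(np.sin(t), (20, 1))
        assert coherence_rho(v) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_scales_as_inverse_sqrt_N(self):
        rng = np.random.default_rng(11)
        N, T = 1000, 10_000
        v = rng.standard_normal((N, T))
        rho = coherence_rho(v)
        # Var of the mean of N unit-variance signals is 1/N; the sampling
        # error of rho over T samples is ~ rho/sqrt(2T)
        se = (N**-0.5) / np.sqrt(2 * T)
        assert abs(rho - N**-0.5) < 3 * se + 0.1 * N**-0.5

    def test_common_signal_plus_equal_noise_gives_sqrt_half(self):
        rng = np.random.default_rng(12)
        t = np.arange(10_000) * 0.01
        common = np.sqrt(2.0) * np.sin(2 * np.pi * 0.7 * t)  # unit variance
        v = common + rng.standard_normal((400, t.size))
        assert coherence_rho(v) == pytest.approx(np.sqrt(0.5), rel=0.05)

    def test_degenerate_traces_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            coherence_rho(np.ones((5, 50)))

    def test_bounds(self):
        rng = np.random.default_rng(13)
        v = rng.standard_normal((30, 400)) + 0.5 * np.sin(np.arange(400) * 0.1)
        assert 0.0 <= coherence_rho(v) <= 1.0 + 1e-9


class TestIsiCv:
    def test_periodic_train_has_zero_cv(self):
        raster = _raster_from_trains([np.arange(0.0, 1000.0, 10.0)])
        cv, pop = isi_cv(raster, "e")
        assert cv[0] == pytest.approx(0.0, abs=1e-12)
        assert pop == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_has_unit_cv(self):
        rng = np.random.default_rng(14)
        isis = rng.exponential(10.0, 10_000)
        raster = _raster_from_trains([np.cumsum(isis)])
        _, pop = isi_cv(raster, "e")
        assert pop == pytest.approx(1.0, abs=0.03)

    def test_gamma_renewal_cv_is_inverse_sqrt_shape(self):
        rng = np.random.default_rng(15)
        for shape in (2.0, 4.0):
            isis = rng.gamma(shape, 1.0, 20_000)
            raster = _raster_from_trains([np.cumsum(isis)])
            _, pop = isi_cv(raster, "e")
            assert pop == pytest.approx(shape**-0.5, rel=0.05)

    def test_sparse_trains_excluded_from_population_average(self):
        raster = _raster_from_trains(
            [np.array([1.0, 2.0]), np.arange(0.0, 100.0, 5.0)]
        )
        cv, pop = isi_cv(raster, "e")
        assert np.isnan(cv[0])
        assert pop == pytest.approx(0.0, abs=1e-12)


class TestPopulationRateTrace:
    def test_empty_raster_gives_zero_trace(self):
        raster = SpikeRaster(
            np.empty(0), np.empty(0, int), np.empty(0, int), 10, 5, 100.0
        )
        tr = population_rate_trace(raster, 1.0)
        assert np.all(tr.R_e == 0) and np.all(tr.R_i == 0)

    def test_exact_spike_conservation(self):
        rng = np.random.default_rng(16)
        trains = [np.sort(rng.uniform(0, 500, rng.integers(5, 50))) for _ in range(20)]
        raster = _raster_from_trains(trains, duration=500.0)
        tr = population_rate_trace(raster, 2.0)
        assert tr.R_e.sum() * 2.0 * 20 == pytest.approx(raster.n_spikes, abs=1e-9)

    def test_constant_rate_poisson_recovery(self):
        rng = np.random.default_rng(17)
        N, T_ms, rate_hz = 1000, 10_000.0, 10.0
        n = rng.poisson(rate_hz * T_ms / 1000.0 * N)
        times = np.sort(rng.uniform(0, T_ms, n))
        neuron = rng.integers(0, N, n)
        raster = SpikeRaster(times, neuron, np.zeros(n, int), N, 1, T_ms)
        tr = population_rate_trace(raster, 1.0)
        assert tr.R_e.mean() * 1000.0 == pytest.approx(rate_hz, abs=0.3)


class TestPowerSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(20_000) * 0.01  # 10 ms sampling
        x = np.sin(2 * np.pi * 3.0 * t)
        spec = power_spectrum(x, 10.0, 10_000)
        assert spec.freqs_hz[np.argmax(spec.power)] == pytest.approx(3.0, abs=spec.resolution_hz)

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(10_000)
        spec = power_spectrum(x, 10.0, 10_000)
        var = (x - x.mean()).var()
        assert spec.power.sum() == pytest.approx(var, rel=1e-8)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(50_000)
        spec = power_spectrum(x, 10.0, 10_000)
        f = spec.freqs_hz
        low = spec.power[(f > 0.1) & (f < 1.0)].mean()
        high = spec.power[(f > 1.0) & (f < 10.0)].mean()
        assert 0.5 < low / high < 2.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            power_spectrum(np.zeros(100), 10.0, 10_000)


def _two_tone(nu1, nu2, n=100_000, dt_ms=10.0, mix=0.02, seed=20):
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt_ms / 1000.0
    x = np.sin(2 * np.pi * nu1 * t) + 0.6 * np.sin(2 * np.pi * nu2 * t + 1.0)
    x = x + mix * x**2 + 0.01 * rng.standard_normal(n)
    return x


class TestFundamentalFrequencies:
    def test_quasi_periodic_pair_not_locked(self):
        # frequency ratio near the golden mean: no small-rational locking
        nu1, nu2 = 1.3, 1.3 / 1.6180339887
        spec = power_spectrum(_two_tone(nu1, nu2), 10.0, 10_000)
        pair = fundamental_frequencies(spec)
        assert pair.nu1_hz == pytest.approx(nu1, abs=2 * spec.resolution_hz)
        assert pair.nu2_hz == pytest.approx(nu2, abs=2 * spec.resolution_hz)
        assert not pair.locked

    def test_four_to_one_ratio_locks(self):
        spec = power_spectrum(_two_tone(1.2, 0.3, mix=0.05), 10.0, 10_000)
        pair = fundamental_frequencies(spec, max_order=3)
        assert pair.locked
        assert pair.locking_order == (1, 4)

    def test_single_tone_has_no_second_fundamental(self):
        t = np.arange(20_000) * 0.01
        x = np.sin(2 * np.pi * 2.0 * t) + 0.3 * np.sin(2 * np.pi * 4.0 * t)
        pair = fundamental_frequencies(power_spectrum(x, 10.0, 10_000))
        assert pair.nu1_hz == pytest.approx(2.0, abs=0.02)
        assert pair.nu2_hz is None

    def test_featureless_spectrum_raises(self):
        rng = np.random.default_rng(21)
        spec = power_spectrum(rng.standard_normal(10_000), 10.0, 10_000)
        with pytest.raises(ValueError, match="no oscillation"):
            fundamental_frequencies(spec, background_factor=50.0)


class TestRateDistribution:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(22)
        mu, sigma, N = np.log(8.0), 0.5, 10_000
        rates = np.exp(rng.normal(mu, sigma, N))
        T_ms = 100_000.0
        counts = rng.poisson(rates * T_ms / 1000.0)
        trains = []
        for c in counts:
            trains.append(np.sort(rng.uniform(0, T_ms, c)))
        raster = _raster_from_trains(trains, duration=T_ms)
        d = rate_distribution(raster, "e")
        se_mu = sigma / np.sqrt(N)
        assert d.mu_log == pytest.approx(mu, abs=3 * se_mu + 0.02)
        assert d.sigma_log == pytest.approx(sigma, rel=0.1)
        assert d.fit_mean_hz == pytest.approx(np.exp(mu + sigma**2 / 2), rel=0.1)

    def test_fully_silent_population(self):
        raster = SpikeRaster(
            np.empty(0), np.empty(0, int), np.empty(0, int), 50, 1, 1000.0
        )
        d = rate_distribution(raster, "e")
        assert d.silent_fraction == 1.0
        assert d.mu_log is None

    def test_silent_fraction_uses_activity_threshold(self):
        # 100 s window: 1 spike = 0.01 Hz (active); 0 spikes = silent
        trains = [np.array([1.0])] * 3 + [np.array([])] * 7
        raster = _raster_from_trains(trains, duration=100_000.0)
        d = rate_distribution(raster, "e")
        assert d.silent_fraction == pytest.approx(0.7)


class TestBurstDelay:
    def _periodic(self, shift_ms=0.0, period=100.0, n=30, dt=1.0):
        t = np.arange(0, n * period, dt)
        base = np.cos(2 * np.pi * (t / period))
        shifted = np.cos(2 * np.pi * ((t - shift_ms) / period))
        return base, shifted, dt

    def test_identical_traces_have_zero_delay(self):
        a, _, dt = self._periodic()
        delay, disp = burst_delay(a, a, dt)
        assert delay == pytest.approx(0.0, abs=dt)
        assert disp == pytest.approx(0.0, abs=dt)

    def test_constructed_shift_is_recovered(self):
        a, b, dt = self._periodic(shift_ms=7.0)
        delay, _ = burst_delay(a, b, dt)
        assert delay == pytest.approx(7.0, abs=dt)

    def test_antisymmetry_under_trace_swap(self):
        a, b, dt = self._periodic(shift_ms=12.0)
        d_ab, _ = burst_delay(a, b, dt)
        d_ba, _ = burst_delay(b, a, dt)
        assert d_ab == pytest.approx(-d_ba, abs=2 * dt)

    def test_near_simultaneous_bursts_read_as_zero(self):
        # sub-sample shift: statistically indistinguishable from zero
        a, b, dt = self._periodic(shift_ms=0.3, dt=1.0)
        delay, disp = burst_delay(a, b, dt)
        assert abs(delay) <= 1.0

    def test_flat_traces_raise(self):
        with pytest.raises(ValueError, match="not oscillatory"):
            burst_delay(np.ones(1000), np.ones(1000), 1.0)
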