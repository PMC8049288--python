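import numpy as np
import pytest

from delaycomm import fixtures, measures, netsim
from delaycomm.errors import (
    InsufficientDataError,
    InsufficientOscillationError,
    InvalidInputError,
)


def _raster_from_times(times, ids, n_neurons, duration, pop=0):
    order = np.argsort(times)
    t = np.asarray(times, float)[order]
    return netsim.SpikeRaster(
        times=t, neuron_ids=np.asarray(ids)[order],
        pop_ids=np.full(len(t), pop), duration=duration, dt=0.01,
        n_neurons=n_neurons,
    )


class TestFiringRate:
    def test_single_spike_gives_unit_symmetric_bump(self):
        r = measures.firing_rate(
            _raster_from_times([50.0], [0], 1, 100.0), kernel_sigma=2.0
        )
        i = np.argmax(r.r)
        assert r.t[i] == pytest.approx(50.0, abs=0.1)
        assert r.r[i] == pytest.approx(1.0, abs=1e-6)
        # symmetry of the bump
        w = 30
        assert np.allclose(r.r[i - w : i], r.r[i + w : i : -1], atol=1e-6)

    def test_coincident_spikes_add(self):
        r = measures.firing_rate(
            _raster_from_times([50.0, 50.0], [0, 1], 2, 100.0)
        )
        assert r.r.max() == pytest.approx(2.0, abs=1e-6)

    def test_rate_bounded_by_spike_count(self):
        rng = np.random.default_rng(0)
        k = 57
        raster = _raster_from_times(
            rng.uniform(0, 200, k), rng.integers(0, 10, k), 10, 200.0
        )
        for sigma in (0.5, 2.0, 20.0):
            r = measures.firing_rate(raster, kernel_sigma=sigma)
            assert r.r.max() <= k + 1e-9

    def test_empty_raster_gives_zero_series(self):
        r = measures.firing_rate(_raster_from_times([], [], 5, 100.0))
        assert not r.r.any()


class TestPeaksAndCoherency:
    def test_periodic_fixture_period_recovered_exactly(self):
        raster = fixtures.periodic_raster(N=50, period=14.0, duration=600.0)
        rate = measures.firing_rate(raster)
        _, T = measures.detect_peaks(rate)
        assert T == pytest.approx(14.0, abs=0.05)

    def test_constant_rate_is_insufficient_oscillation(self):
        flat = measures.RateSeries(t=np.arange(0, 100.0, 0.1),
                                   r=np.ones(1000), kernel_sigma=2.0)
        with pytest.raises(InsufficientOscillationError):
            measures.detect_peaks(flat)

    def test_full_participation_gives_unit_coherency(self):
        raster = fixtures.periodic_raster(N=40, period=14.0, duration=600.0)
        rate = measures.firing_rate(raster)
        assert measures.coherency(rate, 40) == pytest.approx(1.0, abs=0.01)

    def test_half_participation_halves_coherency(self):
        raster = fixtures.periodic_raster(
            N=200, period=14.0, participation=0.5, duration=600.0, seed=1
        )
        rate = measures.firing_rate(raster)
        assert measures.coherency(rate, 200) == pytest.approx(0.5, abs=0.05)

    def test_too_few_peaks_rejected(self):
        raster = fixtures.periodic_raster(N=10, period=14.0, duration=100.0)
        rate = measures.firing_rate(raster)
        with pytest.raises(InsufficientDataError):
            measures.coherency(rate, 10)


class TestZeroLagCov:
    def test_hand_computed_example(self):
        assert measures.zero_lag_cov([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_series_gives_zero(self):
        assert measures.zero_lag_cov([1, 2, 3], [5, 5, 5]) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert measures.zero_lag_cov(x, y) == pytest.approx(
            measures.zero_lag_cov(y, x), rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            measures.zero_lag_cov([1, 2], [1, 2, 3])


class TestDelayedMutualInformation:
    def test_self_information_is_entropy(self):
        # balanced binary sequence: H = 1 bit, enumerable by hand
        x = np.tile([0.0, 1.0], 500)
        c = measures.delayed_mutual_information(
            x, x, dt=1.0, lags=np.array([0.0]), n_bins=2
        )
        assert c.dmi[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_below_plugin_bias_bound(self):
        rng = np.random.default_rng(2)
        n, bins = 100_000, 16
        x, y = rng.random(n), rng.random(n)
        c = measures.delayed_mutual_information(
            x, y, dt=1.0, lags=np.array([0.0]), n_bins=bins
        )
        bias = (bins - 1) ** 2 / (2 * n * np.log(2))
        assert c.dmi[0] < 3 * bias  # small-sample bias scale, not signal

    def test_gaussian_pair_converges_to_binned_information(self):
        # the plug-in estimator targets the *discretized* mutual
        # information; compute that limit exactly by integrating the
        # bivariate normal over the same bin grid and compare
        from scipy.stats import multivariate_normal

        rho, bins = 0.9, 16
        x, y, mi_cont = fixtures.gaussian_pair(100_000, rho=rho, seed=3)
        c = measures.delayed_mutual_information(
            x, y, dt=1.0, lags=np.array([0.0]), n_bins=bins
        )
        mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
        ex = np.linspace(x.min(), x.max(), bins + 1)
        ey = np.linspace(y.min(), y.max(), bins + 1)
        cdf = np.array([[mvn.cdf([a, b]) for b in ey] for a in ex])
        P = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        P = np.clip(P, 0, None)
        P /= P.sum()
        px, py = P.sum(1), P.sum(0)
        m = P > 0
        mi_binned = np.sum(P[m] * np.log2(P[m] / (px[:, None] * py[None, :])[m]))
        assert c.dmi[0] == pytest.approx(mi_binned, rel=0.02)
        # quantization only loses information: binned MI sits below the
        # continuous closed form, and refining the bins closes the gap
        assert c.dmi[0] < mi_cont
        c64 = measures.delayed_mutual_information(
            x, y, dt=1.0, lags=np.array([0.0]), n_bins=64
        )
        assert c64.dmi[0] == pytest.approx(mi_cont, rel=0.10)

    def test_nonnegative_and_time_reversal_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        y = fixtures.lagged_copy(x, 5, noise_sd=0.5, seed=5)
        lags = np.arange(-10.0, 10.5, 1.0)
        c = measures.delayed_mutual_information(x, y, dt=1.0, lags=lags)
        assert (c.dmi >= 0).all()
        c_rev = measures.delayed_mutual_information(
            x[::-1], y[::-1], dt=1.0, lags=np.array([0.0])
        )
        assert c_rev.dmi[0] == pytest.approx(c.dmi[list(lags).index(0.0)],
                                             abs=1e-12)

    def test_lagged_copy_peak_and_flow_direction(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(5000)
        y = fixtures.lagged_copy(x, 5)
        lags = np.arange(-10.0, 10.5, 1.0)
        cxy = measures.delayed_mutual_information(x, y, dt=1.0, lags=lags)
        assert lags[np.argmax(cxy.dmi)] == 5.0
        assert cxy.net_flow > 0
        cyx = measures.delayed_mutual_information(y, x, dt=1.0, lags=lags)
        assert lags[np.argmax(cyx.dmi)] == -5.0
        # dMI_xy(d) = dMI_yx(-d) makes the net flow flip sign exactly
        assert cyx.net_flow == pytest.approx(-cxy.net_flow, rel=1e-9)

    def test_invalid_bins_rejected(self):
        with pytest.raises(InvalidInputError):
            measures.delayed_mutual_information(
                np.ones(100), np.ones(100), dt=1.0, n_bins=1
            )


class TestNetInformation:
    def test_even_curve_integrates_to_zero(self):
        lags = np.arange(-5.0, 5.5, 0.5)
        c = measures.DMICurve(lags=lags, dmi=np.abs(lags), n_bins=4)
        assert measures.net_information(c) == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_curve_equals_positive_integral(self):
        lags = np.arange(-5.0, 5.5, 0.5)
        dmi = np.where(lags > 0, 1.0, 0.0)
        c = measures.DMICurve(lags=lags, dmi=dmi, n_bins=4)
        expected = np.trapezoid(dmi[lags >= 0], lags[lags >= 0])
        assert measures.net_information(c) == pytest.approx(expected)

    def test_asymmetric_grid_rejected(self):
        c = measures.DMICurve(lags=np.array([-1.0, 0.0, 2.0]),
                              dmi=np.zeros(3), n_bins=4)
        with pytest.raises(InvalidInputError):
            measures.net_information(c)


class TestLocking:
    def _two_pop(self, period1, period2, offset):
        a = fixtures.periodic_raster(N=50, period=period1, duration=2500.0,
                                     jitter_sd=0.2, seed=7, pop=0)
        b = fixtures.periodic_raster(N=50, period=period2, duration=2500.0,
                                     jitter_sd=0.2, seed=8, pop=1)
        times = np.concatenate([a.times, b.times + offset])
        ids = np.concatenate([a.neuron_ids, b.neuron_ids + 50])
        pops = np.concatenate([a.pop_ids, b.pop_ids])
        order = np.argsort(times)
        keep = times[order] < 2500.0
        return netsim.SpikeRaster(
            times=times[order][keep], neuron_ids=ids[order][keep],
            pop_ids=pops[order][keep], duration=2500.0, dt=0.01,
            n_neurons=100,
        )

    def test_common_period_fixed_offset_is_locked(self):
        raster = self._two_pop(14.0, 14.0, offset=3.5)  # quarter cycle
        lock = measures.assess_locking(raster)
        assert lock.is_locked
        assert lock.freq_ratio == pytest.approx(1.0, abs=1e-3)
        # population 1 fires 3.5 ms before population 2: it leads by pi/2
        assert abs(lock.phase_diff) == pytest.approx(np.pi / 2, abs=0.15)

    def test_detuned_periods_not_locked_and_phase_undefined(self):
        raster = self._two_pop(13.0, 14.5, offset=0.0)
        lock = measures.assess_locking(raster)
        assert not lock.is_locked
        assert np.isnan(lock.phase_diff)
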