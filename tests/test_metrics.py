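import numpy as np
import pytest

from spikecoding import (
    Network,
    SimResult,
    coverage_gap,
    make_smooth_noise,
    poisson_matched_error,
    rate_to_hz,
    simulate,
    spike_stats,
    tuning_curves,
)
from spikecoding.metrics import TAU_SECONDS


def _raster(spikes, N, n_steps, dt=1e-3, seed=0):
    spikes = np.asarray(spikes, dtype=np.int64).reshape(-1, 2)
    return SimResult(spikes=spikes, r=np.zeros((N, n_steps)), dt=dt, seed=seed)


class TestSpikeStats:
    def test_periodic_train_has_zero_cv(self):
        ev = [[t, 0] for t in range(100, 5000, 200)]
        st = spike_stats(_raster(ev, 1, 5000))
        assert st.cv_isi[0] == pytest.approx(0.0, abs=1e-12)

    def test_cv_matches_bruteforce_on_tiny_raster(self):
        times = [3, 10, 31, 45, 90, 160]
        st = spike_stats(_raster([[t, 0] for t in times], 1, 200))
        isis = np.diff(np.array(times) * 1e-3)
        assert st.cv_isi[0] == pytest.approx(isis.std() / isis.mean())

    def test_neurons_with_few_isis_excluded(self):
        st = spike_stats(_raster([[5, 0], [10, 0], [1, 1]], 2, 100))
        assert np.isnan(st.cv_isi).all()  # 2 and 0 ISIs respectively

    def test_rates_in_hz_use_tau_convention(self):
        # 10 spikes over 100 τ = 0.1 spikes/τ = 10 Hz at τ = 10 ms
        ev = [[t, 0] for t in range(0, 100_000, 10_000)]
        st = spike_stats(_raster(ev, 1, 100_000))
        assert st.mean_rate_hz[0] == pytest.approx(0.1 / TAU_SECONDS)

    def test_fano_requires_two_trials(self):
        st = spike_stats(_raster([[5, 0]], 1, 100))
        assert np.isnan(st.fano_factor[0])

    def test_fano_matches_bruteforce_two_trials(self):
        """Hand-checkable FF: windowed counts, variance/mean across trials
        averaged over windows with nonzero mean."""
        n = 10_000  # two 5 τ windows
        a = _raster([[100, 0], [600, 0], [5100, 0]], 1, n)
        b = _raster([[200, 0], [5200, 0], [5300, 0]], 1, n)
        st = spike_stats([a, b], ff_window=5.0)
        counts = np.array([[2, 1], [1, 2]])  # (trial, window)
        ff = np.mean(counts.var(axis=0, ddof=1) / counts.mean(axis=0))
        assert st.fano_factor[0] == pytest.approx(ff)

    def test_duplicated_neurons_fully_correlated(self):
        ev = [[t, k] for t in range(50, 4000, 137) for k in (0, 1)]
        st = spike_stats(_raster(ev, 2, 4000), bin_width=1.0)
        assert st.mean_pairwise_correlation == pytest.approx(1.0)

    def test_poisson_trains_match_poisson_statistics(self):
        """Homogeneous Poisson at 10 Hz for 100 s: CV = 1 ± 0.1,
        FF = 1 ± 0.2, mean pairwise correlation = 0 ± 0.02."""
        rng = np.random.default_rng(42)
        dt, rate_hz, dur_s, N = 1e-3, 10.0, 100.0, 12
        rate_per_tau = rate_hz * TAU_SECONDS
        n = int(dur_s / TAU_SECONDS / dt)
        trials = []
        for trial in range(3):
            hits = rng.random((N, n)) < rate_per_tau * dt
            ev = np.argwhere(hits)  # (neuron, step) pairs
            trials.append(_raster(np.column_stack([ev[:, 1], ev[:, 0]]), N, n))
        st = spike_stats(trials, bin_width=1.0, ff_window=5.0)
        assert np.nanmean(st.cv_isi) == pytest.approx(1.0, abs=0.1)
        assert np.nanmean(st.fano_factor) == pytest.approx(1.0, abs=0.2)
        assert abs(st.mean_pairwise_correlation) < 0.02

    def test_requires_at_least_one_raster(self):
        with pytest.raises(ValueError):
            spike_stats([])


class TestTuningCurves:
    def test_unconnected_neuron_prefers_its_weight_direction(self):
        """A single neuron with F=(1,0) is driven hardest at angle 0."""
        net = Network(F=[[1.0, 0.0]], Omega=[[-1.0]], T=[0.5], dt=1e-3)
        angles = np.arange(-180.0, 180.0, 15.0)
        tc = tuning_curves(net, radius=1.0, angles=angles, duration_per_angle=10.0)
        assert angles[np.argmax(tc[0])] == pytest.approx(0.0, abs=15.0)

    def test_zero_weights_zero_rates(self):
        net = Network(F=np.zeros((3, 2)), Omega=-np.eye(3), T=np.full(3, 0.5), dt=1e-3)
        tc = tuning_curves(net, 1.0, np.arange(0, 360, 90.0), duration_per_angle=10.0)
        assert not tc.any()

    def test_rotation_equivariance(self):
        """Rotating all feedforward rows by 90° circularly shifts the
        tuning matrix on a matching angle grid."""
        rng = np.random.default_rng(3)
        F = rng.standard_normal((6, 2))
        F /= np.linalg.norm(F, axis=1, keepdims=True)
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90°
        angles = np.arange(-180.0, 180.0, 30.0)
        net_a = Network(F=F, Omega=-np.eye(6), T=np.full(6, 0.5), dt=1e-3)
        net_b = Network(F=F @ rot.T, Omega=-np.eye(6), T=np.full(6, 0.5), dt=1e-3)
        tc_a = tuning_curves(net_a, 1.0, angles, duration_per_angle=10.0)
        tc_b = tuning_curves(net_b, 1.0, angles, duration_per_angle=10.0)
        assert np.allclose(np.roll(tc_a, 3, axis=1), tc_b)


class TestCoverageGap:
    def test_quadrant_coverage(self):
        assert coverage_gap([0.0, 90.0, 180.0, 270.0]) == pytest.approx(90.0)

    def test_degenerate_identical_angles(self):
        assert coverage_gap([30.0, 30.0, 30.0]) == pytest.approx(360.0)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_uniform_angles(self, n):
        assert coverage_gap(np.arange(n) * 360.0 / n) == pytest.approx(360.0 / n)

    def test_needs_two_angles(self):
        with pytest.raises(ValueError):
            coverage_gap([10.0])


class TestPoissonMatchedError:
    def test_zero_rates_give_signal_power(self):
        sig = make_smooth_noise(2, 20.0, 1e-3, seed=0)
        res = SimResult(spikes=np.empty((0, 2), dtype=np.int64),
                        r=np.zeros((5, sig.n_steps)), dt=1e-3, seed=0)
        err = poisson_matched_error(res, sig.x, seed=1)
        half = sig.n_steps // 2
        assert err == pytest.approx(np.mean(np.sum(sig.x[:, half:] ** 2, axis=0)))

    def test_reproducible_by_seed(self, small_balanced_net, noise_signal):
        res = simulate(small_balanced_net, noise_signal, seed=2)
        a = poisson_matched_error(res, noise_signal.x, seed=9)
        b = poisson_matched_error(res, noise_signal.x, seed=9)
        assert a == b

    def test_error_shrinks_with_population_size_on_average(self):
        """More Poisson neurons at the same per-neuron rate decode better:
        Monte-Carlo over seeds, comparing 5 vs 40 neurons."""
        sig = make_smooth_noise(2, 30.0, 1e-3, seed=3)
        n = sig.n_steps

        def err(N, seed):
            res = SimResult(spikes=np.empty((0, 2), dtype=np.int64),
                            r=np.zeros((N, n)), dt=1e-3, seed=0)
            return poisson_matched_error(
                res, sig.x, seed=seed, rates=np.full(N, 0.2)
            )

        small = np.mean([err(5, s) for s in range(5)])
        big = np.mean([err(40, s) for s in range(5)])
        assert big < small


def test_rate_conversion():
    assert rate_to_hz(0.05) == pytest.approx(5.0)
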